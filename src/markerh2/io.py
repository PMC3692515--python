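"""File formats: VCF marker genotypes, TSV pedigree/phenotypes/QTL
genotypes, square and GRM-style kinship text, and run manifests.

Every pipeline stage is readable and writable through files alone so that
intermediate objects can be cross-checked with external mixed-model or
population-genetics software. Unknown parents are encoded as ``0`` in the
pedigree TSV (PLINK .fam convention).
"""

from __future__ import annotations

import datetime
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import __version__
from .config import SimulationConfig
from .relatedness import KinshipMatrix
from .simulator import UNKNOWN_PARENT, PedigreeRecord, PopulationState

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
    "write_qtl_genotypes",
    "write_kinship_square",
    "read_kinship_square",
    "write_kinship_grm",
    "read_kinship_grm",
    "write_manifest",
    "write_population",
]


class VcfFormatError(ValueError):
    pass


def write_vcf(marker_genotypes: np.ndarray, ids, path: str | Path) -> None:
    """Write biallelic marker genotypes as uncompressed VCF 4.2.

    One pseudo-contig ``1``; site i at position i+1 with REF=A, ALT=T;
    unphased GT per sample.
    """
    g = np.asarray(marker_genotypes)
    n, L, _ = g.shape
    header = pysam.VariantHeader()
    header.add_line("##source=markerh2")
    header.add_line(f"##contig=<ID=1,length={L + 1}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in ids:
        header.add_sample(str(s))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for l in range(L):
            rec = vcf.new_record(
                contig="1", start=l, stop=l + 1, alleles=("A", "T"), id=f"snp{l}"
            )
            for k, s in enumerate(ids):
                rec.samples[str(s)]["GT"] = (int(g[k, l, 0]), int(g[k, l, 1]))
                rec.samples[str(s)].phased = False
            vcf.write(rec)


def read_vcf(path: str | Path):
    """Read a biallelic VCF into ((n, L, 2) allele indices, sample ids).

    Multi-allelic sites and missing GT calls are rejected explicitly (the
    simulator never emits either).
    """
    with pysam.VariantFile(str(path)) as vcf:
        ids = list(vcf.header.samples)
        rows = []
        for line_no, rec in enumerate(vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfFormatError(
                    f"{path}: site {rec.id or rec.pos} (record {line_no}) is not biallelic"
                )
            site = []
            for s in ids:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt) or len(gt) != 2:
                    raise VcfFormatError(
                        f"{path}: missing GT for sample {s} at record {line_no}"
                    )
                site.append(gt)
            rows.append(site)
    if not rows:
        raise VcfFormatError(f"{path}: no variant records")
    g = np.array(rows, dtype=np.int8)  # (L, n, 2)
    return np.transpose(g, (1, 0, 2)), ids


def _label(global_id: int, N: int) -> str:
    return f"gen{global_id // N}_ind{global_id % N}"


def write_pedigree(pedigree, path: str | Path, N: int | None = None) -> None:
    """4-column TSV: id, sire, dam, generation; unknown parents written 0."""
    if N is None:
        N = sum(1 for r in pedigree if r.generation == 0)

    def fmt(pid):
        return "0" if pid == UNKNOWN_PARENT else _label(pid, N)

    df = pd.DataFrame(
        {
            "id": [_label(r.id, N) for r in pedigree],
            "sire": [fmt(r.sire) for r in pedigree],
            "dam": [fmt(r.dam) for r in pedigree],
            "generation": [r.generation for r in pedigree],
        }
    )
    df.to_csv(path, sep="\t", index=False)


_LABEL_RE = re.compile(r"^gen(\d+)_ind(\d+)$")


def read_pedigree(path: str | Path):
    """Read a pedigree TSV back into PedigreeRecord objects."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gens = df["generation"].astype(int)
    per_gen = gens.value_counts().to_dict()
    N = per_gen.get(0)
    if N is None:
        raise ValueError(f"{path}: no founder (generation 0) rows")

    def parse(label, generation):
        if label == "0":
            return UNKNOWN_PARENT
        m = _LABEL_RE.match(label)
        if not m:
            raise ValueError(f"{path}: malformed individual label {label!r}")
        return int(m.group(1)) * N + int(m.group(2))

    return [
        PedigreeRecord(
            id=parse(row["id"], g),
            sire=parse(row["sire"], g),
            dam=parse(row["dam"], g),
            generation=g,
        )
        for (_, row), g in zip(df.iterrows(), gens)
    ]


def write_phenotypes(ids, values, path: str | Path) -> None:
    pd.DataFrame({"id": list(ids), "value": np.asarray(values, dtype=float)}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    return list(df["id"].astype(str)), df["value"].to_numpy(dtype=float)


def write_qtl_genotypes(qtl_genotypes: np.ndarray, ids, path: str | Path) -> None:
    """Multi-allelic QTL genotypes as TSV: two allele-index columns per locus."""
    g = np.asarray(qtl_genotypes)
    n, L, _ = g.shape
    flat = g.reshape(n, 2 * L)
    cols = [f"qtl{l}_a{c}" for l in range(L) for c in (1, 2)]
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_qtl_genotypes(path: str | Path):
    df = pd.read_csv(path, sep="\t")
    ids = list(df["id"].astype(str))
    mat = df.drop(columns="id").to_numpy(dtype=np.int8)
    n, twoL = mat.shape
    return mat.reshape(n, twoL // 2, 2), ids


def write_kinship_square(K: KinshipMatrix, path: str | Path) -> None:
    """Square TSV with individual ids as header and index."""
    pd.DataFrame(K.values, index=[str(i) for i in K.ids], columns=[str(i) for i in K.ids]).to_csv(
        path, sep="\t", index_label="id"
    )


def read_kinship_square(path: str | Path, source: str = "marker") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(values=df.to_numpy(dtype=float), ids=list(df.columns), source=source)


def write_kinship_grm(K: KinshipMatrix, path: str | Path) -> None:
    """GRM-style long text: 1-based i, j (i >= j), n_loci_used, value."""
    n = K.n
    with open(path, "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{K.n_loci_used}\t{K.values[i, j]:.10g}\n")


def read_kinship_grm(path: str | Path, ids=None, source: str = "marker") -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "n_loci", "value"])
    n = int(df["i"].max())
    values = np.zeros((n, n))
    ii = df["i"].to_numpy(int) - 1
    jj = df["j"].to_numpy(int) - 1
    values[ii, jj] = df["value"].to_numpy(float)
    values[jj, ii] = df["value"].to_numpy(float)
    if ids is None:
        ids = list(range(n))
    return KinshipMatrix(
        values=values, ids=ids, source=source, n_loci_used=int(df["n_loci"].iloc[0])
    )


def read_kinship(path: str | Path, source: str = "marker") -> KinshipMatrix:
    """Accept either the square-TSV or the GRM-style long format."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("id\t"):
        return read_kinship_square(path, source=source)
    return read_kinship_grm(path, source=source)


def write_manifest(out_dir: str | Path, config: SimulationConfig, stage: str, outputs: dict) -> Path:
    """One manifest per output directory: config hash, seed, version, paths."""
    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "config": config.to_dict() if config is not None else None,
        "config_hash": config.digest() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "outputs": {k: str(v) for k, v in outputs.items()},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_population(pop: PopulationState, out_dir: str | Path) -> dict:
    """Persist one replicate: VCF markers, TSV QTLs, pedigree, phenotypes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "markers_vcf": out_dir / "markers.vcf",
        "qtl_tsv": out_dir / "qtl_genotypes.tsv",
        "pedigree_tsv": out_dir / "pedigree.tsv",
        "phenotypes_tsv": out_dir / "phenotypes.tsv",
    }
    write_vcf(pop.marker_genotypes, pop.ids, paths["markers_vcf"])
    write_qtl_genotypes(pop.qtl_genotypes, pop.ids, paths["qtl_tsv"])
    write_pedigree(pop.pedigree, paths["pedigree_tsv"], N=pop.config.N)
    write_phenotypes(pop.ids, pop.phenotypes, paths["phenotypes_tsv"])
    write_manifest(out_dir, pop.config, "simulate", paths)
    return paths
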