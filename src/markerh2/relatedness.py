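"""Pairwise kinship from pedigrees and from marker genotypes.

Two routes to the same quantity:

* **Pedigree kinship** (expected identity by descent), by the classical
  recursion on a generation-ordered pedigree: founders have self-kinship
  1/2 and mutual kinship 0; thereafter
  phi(i, i) = (1 + phi(sire_i, dam_i)) / 2 and
  phi(i, j) = [phi(sire_i, j) + phi(dam_i, j)] / 2.

* **Marker kinship** with the Loiselle estimator, a sample-allele-frequency
  referenced coefficient that does not assume Hardy-Weinberg equilibrium
  and is robust to rare alleles. For individuals i, j:

      K_ij = sum_l sum_a [(p_ila - pbar_la)(p_jla - pbar_la)
                          + pbar_la (1 - pbar_la) / (n - 1)]
             / sum_l sum_a pbar_la (1 - pbar_la)

  where p_ila in {0, 1/2, 1} is half the allele dosage and pbar_la the
  sample frequency. The diagonal is computed by the same formula with
  i = j, so individual homozygosity feeds the self-comparison.

The animal model consumes the transform G* = 2 K / (1 + F), repaired to the
nearest positive semi-definite matrix by clipping negative eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulator import UNKNOWN_PARENT, PedigreeRecord

__all__ = [
    "KinshipMatrix",
    "InbreedingSummary",
    "pedigree_kinship",
    "pedigree_inbreeding",
    "equilibrium_inbreeding",
    "loiselle_kinship",
    "truncate_nonnegative",
    "covariance_structure",
]

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    pass


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship with provenance.

    ``source`` is one of pedigree / marker / qtl; ``diagonal_convention``
    documents what the self-comparison entries mean.
    """

    values: np.ndarray
    ids: list
    source: str
    diagonal_convention: str = ""
    truncated: bool = False
    n_loci_used: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length must match matrix order")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (each unordered pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class InbreedingSummary:
    per_individual_F: np.ndarray
    origin: str  # pedigree | equilibrium
    mean_F: float = field(default=None)

    def __post_init__(self) -> None:
        self.per_individual_F = np.asarray(self.per_individual_F, dtype=float)
        if self.mean_F is None:
            self.mean_F = float(self.per_individual_F.mean())


def _pedigree_by_generation(pedigree):
    """Group records by generation and validate parent links."""
    gens: dict[int, list[PedigreeRecord]] = {}
    for rec in pedigree:
        gens.setdefault(rec.generation, []).append(rec)
    order = sorted(gens)
    if order and order[0] != 0:
        raise PedigreeError("pedigree must start at generation 0")
    id_to_pos: dict[int, tuple[int, int]] = {}
    for g in order:
        for k, rec in enumerate(gens[g]):
            id_to_pos[rec.id] = (g, k)
    for g in order:
        for rec in gens[g]:
            if g == 0:
                if rec.sire != UNKNOWN_PARENT or rec.dam != UNKNOWN_PARENT:
                    raise PedigreeError(f"founder {rec.id} has named parents")
                continue
            for parent in (rec.sire, rec.dam):
                if parent not in id_to_pos:
                    raise PedigreeError(f"parent {parent} of {rec.id} absent from pedigree")
                pg, _ = id_to_pos[parent]
                if pg != g - 1:
                    raise PedigreeError(
                        f"parent {parent} of {rec.id} is in generation {pg}, expected {g - 1}"
                    )
    return gens, order, id_to_pos


def _kinship_recursion(pedigree, target_generation):
    """Run the generation-wise kinship recursion up to the target.

    Because every parent belongs to the previous generation, only one
    within-generation matrix needs to be carried. Returns
    (phi_target, F_target, records_target).
    """
    gens, order, id_to_pos = _pedigree_by_generation(pedigree)
    if target_generation not in gens:
        raise PedigreeError(f"generation {target_generation} absent from pedigree")

    n0 = len(gens[0])
    phi = np.eye(n0) * 0.5
    F = np.zeros(n0)
    for g in order[1 : target_generation + 1]:
        recs = gens[g]
        s = np.array([id_to_pos[r.sire][1] for r in recs])
        d = np.array([id_to_pos[r.dam][1] for r in recs])
        F_new = phi[s, d]
        phi_new = 0.25 * (phi[np.ix_(s, s)] + phi[np.ix_(s, d)] + phi[np.ix_(d, s)] + phi[np.ix_(d, d)])
        np.fill_diagonal(phi_new, 0.5 * (1.0 + F_new))
        phi, F = phi_new, F_new
    return phi, F, gens[target_generation]


def pedigree_kinship(pedigree, target_generation: int) -> KinshipMatrix:
    """Expected-IBD kinship among the individuals of one generation."""
    phi, _, recs = _kinship_recursion(pedigree, target_generation)
    return KinshipMatrix(
        values=phi,
        ids=[r.id for r in recs],
        source="pedigree",
        diagonal_convention="self-kinship (1 + F_i)/2",
    )


def pedigree_inbreeding(pedigree, target_generation: int) -> InbreedingSummary:
    """F_i = kinship of the parents; founders have F = 0."""
    _, F, _ = _kinship_recursion(pedigree, target_generation)
    return InbreedingSummary(per_individual_F=F, origin="pedigree")


def equilibrium_inbreeding(S: float) -> float:
    """Equilibrium inbreeding coefficient S / (2 - S) under selfing rate S."""
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"selfing rate must be in [0, 1] (got {S})")
    return S / (2.0 - S)


def _allele_dosage_matrix(genotypes: np.ndarray):
    """Half-dosage matrix p_ila (n x total alleles) plus locus allele counts."""
    g = np.asarray(genotypes)
    n, L, _ = g.shape
    n_alleles = int(g.max()) + 1
    # one-hot of both allele copies, averaged -> entries in {0, 1/2, 1}
    P = np.zeros((n, L * n_alleles))
    cols = g[:, :, 0] * 1 + np.arange(L)[None, :] * n_alleles
    np.add.at(P, (np.repeat(np.arange(n), L), cols.ravel()), 0.5)
    cols = g[:, :, 1] * 1 + np.arange(L)[None, :] * n_alleles
    np.add.at(P, (np.repeat(np.arange(n), L), cols.ravel()), 0.5)
    return P, n_alleles


def loiselle_kinship(genotypes: np.ndarray, ids=None, source: str = "marker") -> KinshipMatrix:
    """Loiselle kinship for biallelic or multi-allelic genotypes.

    Parameters
    ----------
    genotypes : (n, L, 2) integer allele indices.
    ids : row labels (defaults to 0..n-1).
    source : provenance tag, ``marker`` or ``qtl``.

    Loci monomorphic in the sample contribute nothing to numerator or
    denominator and are effectively dropped (their count is logged).
    """
    g = np.asarray(genotypes)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError("genotypes must have shape (n, L, 2)")
    n, L, _ = g.shape
    if n < 2:
        raise ValueError("need at least two individuals")

    P, _ = _allele_dosage_matrix(g)
    pbar = P.mean(axis=0)
    w = pbar * (1.0 - pbar)  # per-allele weight pbar(1-pbar)
    denom = float(w.sum())
    if denom <= 0.0:
        raise ValueError("all loci are monomorphic in the sample; kinship undefined")
    mono = (g == g[0, :, 0][None, :, None]).all(axis=(0, 2))
    n_mono = int(mono.sum())
    if n_mono:
        logger.debug("loiselle_kinship: %d loci monomorphic in sample (dropped)", n_mono)

    Pc = P - pbar[None, :]
    correction = float((w / (n - 1)).sum())
    K = (Pc @ Pc.T + correction) / denom
    K = 0.5 * (K + K.T)  # exact symmetry against float round-off
    if ids is None:
        ids = list(range(n))
    return KinshipMatrix(
        values=K,
        ids=list(ids),
        source=source,
        diagonal_convention="Loiselle formula applied with i = j (homozygosity-weighted)",
        n_loci_used=L - n_mono,
    )


def truncate_nonnegative(K: KinshipMatrix) -> KinshipMatrix:
    """Element-wise max(value, 0), the GWAS-style matrix truncation."""
    return KinshipMatrix(
        values=np.maximum(K.values, 0.0),
        ids=list(K.ids),
        source=K.source,
        diagonal_convention=K.diagonal_convention,
        truncated=True,
        n_loci_used=K.n_loci_used,
    )


def covariance_structure(K: KinshipMatrix, F: float) -> np.ndarray:
    """Genetic covariance structure G* = 2 K / (1 + F), repaired to PSD.

    F is the mean inbreeding coefficient of the sample (0 for outcrossing
    populations). Marker-based kinship matrices can have small negative
    eigenvalues; those are clipped to zero (eigenvectors and the remaining
    spectrum untouched) and the clipped mass is logged.
    """
    if not 0.0 <= F < 1.0 + 1e-12:
        raise ValueError(f"mean inbreeding coefficient out of range: {F}")
    G = 2.0 * K.values / (1.0 + F)
    eigval, eigvec = np.linalg.eigh(G)
    if eigval[0] < 0:
        clipped = float(-eigval[eigval < 0].sum())
        logger.debug(
            "covariance_structure: clipped %d negative eigenvalues (mass %.3g)",
            int((eigval < 0).sum()),
            clipped,
        )
        eigval = np.maximum(eigval, 0.0)
        G = (eigvec * eigval[None, :]) @ eigvec.T
        G = 0.5 * (G + G.T)
    return G
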