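"""From per-modality omics matrices to per-patient latent factor vectors.

The condition vector tau for each patient is produced in four steps:

1. drop rows/columns that are entirely zero (quality filter);
2. keep the top fraction of genes by coefficient of variation
   (CV = std / |mean|), computed on a reference modality (expression by
   default — methylation/CNV scales make CV ill-behaved);
3. stack the aligned modality matrices into a patients x genes x modalities
   tensor;
4. factorize the tensor at rank R (default 17) by alternating-least-squares
   CP decomposition, yielding one R-vector of factor scores per patient.

Factor scores are z-scored per factor before use as conditions, because the
downstream inner-product fusion is scale-sensitive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "OmicsTensor",
    "LatentFactorMatrix",
    "drop_all_zero",
    "cv_filter",
    "build_tensor",
    "factorize",
    "read_matrix",
]

MODALITIES = ("expression", "methylation", "cnv")


class EmptinessError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class OmicsMatrix:
    """patients x genes matrix for one modality; ids are ordered and unique."""

    values: pd.DataFrame  # index = patient ids, columns = gene ids
    modality: str

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("duplicated patient or gene identifiers")
        if not np.all(np.isfinite(df.to_numpy(float))):
            raise ValueError("omics values must be finite")

    @property
    def patient_ids(self):
        return list(self.values.index)

    @property
    def gene_ids(self):
        return list(self.values.columns)


@dataclass(frozen=True)
class OmicsTensor:
    """patients x genes x modalities array with aligned id lists per axis."""

    values: np.ndarray
    patient_ids: tuple
    gene_ids: tuple
    modalities: tuple

    def __post_init__(self):
        if self.values.shape != (
            len(self.patient_ids), len(self.gene_ids), len(self.modalities)
        ):
            raise ValueError("tensor shape does not match id lists")


@dataclass
class LatentFactorMatrix:
    """Output of the rank-R factorization: per-patient scores plus companion
    gene/modality loadings and the ALS reconstruction-error trace."""

    scores: np.ndarray            # patients x R
    gene_loadings: np.ndarray     # genes x R
    modality_loadings: np.ndarray  # modalities x R
    patient_ids: tuple
    rank: int
    fit_diagnostics: dict = field(default_factory=dict)

    def condition_matrix(self, standardize: bool = True) -> np.ndarray:
        """Patient factor scores as condition vectors tau (z-scored per
        factor by default)."""
        s = self.scores
        if not standardize:
            return s.copy()
        sd = s.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (s - s.mean(axis=0)) / sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=list(self.patient_ids),
            columns=[f"factor_{i + 1}" for i in range(self.rank)],
        )


def drop_all_zero(m: OmicsMatrix) -> OmicsMatrix:
    """Remove all-zero patients (rows) and genes (columns), iterated to a
    fixed point; errors if nothing survives."""
    df = m.values
    while True:
        arr = df.to_numpy(float)
        if arr.size == 0:
            raise EmptinessError(f"{m.modality}: no nonzero rows/columns remain")
        keep_rows = ~np.all(arr == 0, axis=1)
        keep_cols = ~np.all(arr == 0, axis=0)
        if keep_rows.all() and keep_cols.all():
            return OmicsMatrix(df, m.modality)
        df = df.loc[keep_rows, keep_cols]


def cv_filter(matrices: list[OmicsMatrix], fraction: float = 0.10,
              reference: str = "expression") -> list[str]:
    """Select the ceil(fraction * G) gene ids with the largest coefficient of
    variation on the reference modality.

    CV = std / |mean| (sample std, ddof=1); a gene with mean exactly 0 is
    treated as maximally variable (CV = +inf).  Ties break lexicographically
    by gene id; the returned list is sorted by gene id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    by_mod = {m.modality: m for m in matrices}
    if reference not in by_mod:
        raise ValueError(f"reference modality {reference!r} not supplied")
    df = by_mod[reference].values
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = (std / mean.abs()).to_numpy(float)
    cv[mean.to_numpy() == 0] = np.inf
    k = math.ceil(fraction * df.shape[1])
    order = sorted(zip(df.columns, cv), key=lambda gc: (-gc[1], gc[0]))
    return sorted(g for g, _ in order[:k])


def build_tensor(matrices: list[OmicsMatrix], genes) -> OmicsTensor:
    """Stack modality matrices into a (patient, gene, modality) tensor.

    All id lists are sorted, so the result is invariant to input row/column
    order; a modality missing any requested patient or gene raises an
    alignment error naming the offender.
    """
    if not matrices:
        raise ValueError("need at least one modality")
    genes = sorted(genes)
    patients = sorted(matrices[0].patient_ids)
    modalities = sorted(m.modality for m in matrices)
    by_mod = {m.modality: m for m in matrices}
    slabs = []
    for mod in modalities:
        df = by_mod[mod].values
        missing_p = set(patients) - set(df.index)
        if missing_p:
            raise AlignmentError(
                f"modality {mod!r} is missing patients {sorted(missing_p)[:5]}"
            )
        missing_g = set(genes) - set(df.columns)
        if missing_g:
            raise AlignmentError(
                f"modality {mod!r} is missing genes {sorted(missing_g)[:5]}"
            )
        slabs.append(df.loc[patients, genes].to_numpy(float))
    return OmicsTensor(
        np.stack(slabs, axis=2),
        patient_ids=tuple(patients),
        gene_ids=tuple(genes),
        modalities=tuple(modalities),
    )


# -- CP decomposition by alternating least squares -------------------------


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def factorize(tensor: OmicsTensor, rank: int = 17, max_iters: int = 200,
              tol: float = 1e-8, seed: int = 0) -> LatentFactorMatrix:
    """Rank-R CP decomposition minimising squared reconstruction error.

    Seeded random init; each ALS sweep solves the three linear
    least-squares subproblems in turn, so the reconstruction error is
    monotone non-increasing across the recorded trace.  Stops when the
    relative error improves by less than ``tol``; non-convergence within
    ``max_iters`` sets a warning flag in fit_diagnostics rather than
    raising.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if max_iters < 1:
        raise ValueError("max_iters must be >= 1")
    x = np.asarray(tensor.values, float)
    if not np.all(np.isfinite(x)):
        raise ValueError("tensor entries must be finite")
    if rank > min(x.shape):
        warnings.warn(
            f"rank {rank} exceeds the smallest tensor dimension {min(x.shape)}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    a, b, c = (rng.standard_normal((dim, rank)) for dim in x.shape)
    unfolds = [_unfold(x, m) for m in range(3)]
    norm_x = np.linalg.norm(x)

    def solve(unf, f1, f2):
        kr = _khatri_rao(f1, f2)  # rows ordered to match the unfolding
        gram = (f1.T @ f1) * (f2.T @ f2)
        return np.linalg.lstsq(gram.T, (unf @ kr).T, rcond=None)[0].T

    trace = []
    converged = False
    for _ in range(max_iters):
        a = solve(unfolds[0], b, c)
        b = solve(unfolds[1], a, c)
        c = solve(unfolds[2], a, b)
        # renormalise loadings, absorbing scale into the patient scores
        for f in (b, c):
            nrm = np.linalg.norm(f, axis=0)
            nrm[nrm == 0] = 1.0
            f /= nrm
            a *= nrm
        recon = np.einsum("ir,jr,kr->ijk", a, b, c)
        err = np.linalg.norm(x - recon) / (norm_x if norm_x > 0 else 1.0)
        trace.append(err)
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < tol:
            converged = True
            break
    return LatentFactorMatrix(
        scores=a,
        gene_loadings=b,
        modality_loadings=c,
        patient_ids=tensor.patient_ids,
        rank=rank,
        fit_diagnostics={
            "error_trace": np.asarray(trace),
            "converged": converged,
            "n_iters": len(trace),
            "seed": seed,
        },
    )


def read_matrix(path, modality: str) -> OmicsMatrix:
    """Read a TSV/CSV with patients as rows (first column = patient id) and
    genes as columns."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return OmicsMatrix(df, modality)
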