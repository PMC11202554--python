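"""Ordination of genotype matrices and admixture model-order selection.

PCA operates on the 0/1/2 counted-allele dosage coding, column-centered
without variance scaling; components come from the exact singular value
decomposition, and explained-variance fractions are eigenvalues of the
sample covariance over its trace.  The Evanno second-difference statistic
(delta K) consumes a table of replicate log-probabilities produced by an
external admixture program; the MCMC itself is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import GenotypeMatrix

log = logging.getLogger("snppanel")


@dataclass
class PcaResult:
    samples: list[str]
    populations: list[str]
    coordinates: np.ndarray  # samples x components
    explained: np.ndarray  # fraction of total variance per component
    loadings: np.ndarray  # components x loci
    loci: list[str]


def genotype_pca(
    matrix: GenotypeMatrix,
    missing: str = "mean",
    n_components: int | None = None,
) -> PcaResult:
    """Principal components of the centered genotype dosage matrix.

    Missing dosages are imputed to the locus mean (``missing="mean"``) or
    the locus is dropped entirely (``missing="drop"``).  Each component's
    sign is fixed by making its largest-magnitude loading positive, so
    results are reproducible across runs and locus orderings.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    dos, _ = matrix.dosage_matrix()
    loci = list(matrix.loci)
    nan_cols = np.isnan(dos).any(axis=0)
    if missing == "drop":
        keep = ~nan_cols
        dos = dos[:, keep]
        loci = [l for l, k in zip(loci, keep) if k]
    elif missing == "mean":
        col_mean = np.nanmean(np.where(np.isnan(dos), np.nan, dos), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(dos))
        dos[idx] = col_mean[idx[1]]
    else:
        raise ValueError("missing must be 'mean' or 'drop'")

    centered = dos - dos.mean(axis=0)
    total_var = centered.var(axis=0, ddof=1).sum()
    if total_var <= 0:
        raise ValueError("no variation in genotype matrix")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = centered.shape[0]
    eigvals = s**2 / (n - 1)
    explained = eigvals / total_var
    scores = u * s
    # deterministic sign: largest-|loading| positive per component
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            scores[:, k] *= -1
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
        vt = vt[:n_components]
    pops = [matrix.populations[smp] for smp in matrix.samples]
    return PcaResult(list(matrix.samples), pops, scores, explained, vt, loci)


@dataclass
class EvannoRow:
    k: int
    mean_lnp: float
    sd_lnp: float
    delta_k: float | None


@dataclass
class EvannoResult:
    rows: list[EvannoRow]
    best_k: int | None

    def delta_k(self, k: int) -> float | None:
        for row in self.rows:
            if row.k == k:
                return row.delta_k
        raise KeyError(k)


def evanno_delta_k(table: Mapping[int, Sequence[float]]) -> EvannoResult:
    """Evanno delta K over replicate admixture log-probabilities.

    ``table`` maps each K of a consecutive grid to its replicate lnP
    values (runs paired by index across K).  For interior K,
    delta K = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd(L(K)),
    the sd taken across replicates (ddof=1).  K values where the sd is
    zero are excluded from the argmax with a warning.
    """
    ks = sorted(table)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values for delta K")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K grid must be consecutive, got {ks}")
    for k in ks:
        if len(table[k]) < 2:
            raise ValueError(f"need >= 2 replicates per K for sd; K={k} has {len(table[k])}")
    rows: list[EvannoRow] = []
    for k in ks:
        vals = np.asarray(table[k], dtype=float)
        rows.append(EvannoRow(k, float(vals.mean()), float(vals.std(ddof=1)), None))
    by_k = {r.k: r for r in rows}
    for k in ks[1:-1]:
        n_rep = min(len(table[k - 1]), len(table[k]), len(table[k + 1]))
        prev = np.asarray(table[k - 1][:n_rep], dtype=float)
        here = np.asarray(table[k][:n_rep], dtype=float)
        nxt = np.asarray(table[k + 1][:n_rep], dtype=float)
        second = np.abs(nxt - 2 * here + prev).mean()
        sd = by_k[k].sd_lnp
        if sd == 0:
            log.warning("sd(L) = 0 at K=%d; delta K undefined there", k)
            continue
        by_k[k].delta_k = float(second / sd)
    eligible = [r for r in rows if r.delta_k is not None]
    best_k = max(eligible, key=lambda r: r.delta_k).k if eligible else None
    return EvannoResult(rows, best_k)
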