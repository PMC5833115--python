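"""Probabilistic imputation of missing trait cells.

A missing cell is filled by estimating the probability that it is a zero,

    P(0) = T(z) * P(s) * P(t),

where P(s) = n0/n_s is the observed zero fraction of the cell's species row,
P(t) = n0/n_t the observed zero fraction of its trait column, and
T(z) = n0_total / (n_rows * n_cols) the whole-matrix zero proportion (note the
denominator counts all cells, observed or not, as written).  Cells with
P(0) > 0.5 become 0, otherwise 1.  All statistics are computed once from the
pre-imputation matrix, so the result is independent of fill order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("traitnet")


@dataclass(frozen=True)
class ImputationModel:
    """Zero-probability statistics frozen from a matrix with missing cells."""

    n0_species: np.ndarray  # observed zeros per species
    n_s: np.ndarray         # observed cells per species
    n0_trait: np.ndarray
    n_t: np.ndarray
    n0_total: int
    n_r: int
    n_c: int

    @property
    def T_z(self) -> float:
        """Whole-matrix zero proportion (denominator = all cells)."""
        return self.n0_total / (self.n_r * self.n_c)

    def p_species(self, i: int) -> float:
        if self.n_s[i] == 0:
            raise ValueError(f"species row {i} has no observed cells; P(s) undefined")
        return self.n0_species[i] / self.n_s[i]

    def p_trait(self, j: int) -> float:
        if self.n_t[j] == 0:
            raise ValueError(f"trait column {j} has no observed cells; P(t) undefined")
        return self.n0_trait[j] / self.n_t[j]


def fit_model(m: pd.DataFrame) -> ImputationModel:
    """Freeze the zero-count statistics of a 0/1/NaN trait matrix."""
    x = m.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    zeros = obs & (x == 0)
    return ImputationModel(
        n0_species=zeros.sum(axis=1),
        n_s=obs.sum(axis=1),
        n0_trait=zeros.sum(axis=0),
        n_t=obs.sum(axis=0),
        n0_total=int(zeros.sum()),
        n_r=x.shape[0],
        n_c=x.shape[1],
    )


def cell_zero_probability(model: ImputationModel, i: int, j: int) -> float:
    """P(0) = T(z) * P(s) * P(t) for cell (species i, trait j)."""
    return model.T_z * model.p_species(i) * model.p_trait(j)


def impute(
    m: pd.DataFrame, threshold: float = 0.5, return_audit: bool = False
):
    """Fill every missing cell of a 0/1/NaN matrix; returns an int frame.

    P(0) > threshold imputes 0; P(0) < threshold imputes 1.  An exact tie is
    imputed 1 (the "< threshold sets 1" branch taken as the closed half) and
    logged.  Observed cells are never modified.

    With ``return_audit`` also returns a tidy frame of the per-cell P(0).
    """
    model = fit_model(m)
    x = m.to_numpy(dtype=float).copy()
    miss_i, miss_j = np.nonzero(np.isnan(x))
    audit = []
    for i, j in zip(miss_i, miss_j):
        p0 = cell_zero_probability(model, int(i), int(j))
        if p0 == threshold:
            log.info("P(0) tie at (%s, %s): imputing 1", m.index[i], m.columns[j])
        x[i, j] = 0.0 if p0 > threshold else 1.0
        audit.append((m.index[i], m.columns[j], p0, int(x[i, j])))
    out = pd.DataFrame(x.astype(int), index=m.index, columns=m.columns)
    if return_audit:
        audit_df = pd.DataFrame(audit, columns=["species", "trait", "p_zero", "imputed"])
        return out, audit_df
    return out
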