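"""Survey-weighted aggregation of birth records into areal panels.

Individual birth records carry a DHS-style sampling weight and a neonatal
death indicator (death within 28 days of life).  Aggregation produces, per
areal unit i and survey period t, weighted death counts Y_it and weighted
births at risk N_it; internal standardization then yields expected counts

    E_it = N_it * (sum Y / sum N)

so that the standardized mortality ratio SMR_it = Y_it / E_it averages to 1
over the panel.  The module also computes the weighted neonatal mortality
rate (deaths per 1000 live births) and an iterative variance-inflation-factor
screen for collinear areal covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "ArealPanel",
    "read_birth_records",
    "aggregate",
    "expected_counts",
    "smr",
    "weighted_nmr",
    "indicator_table",
    "vif_screen",
]

#: required columns of a birth-record table; covariates are any extra columns
RECORD_COLUMNS = ("unit_id", "period", "weight", "death")


def read_birth_records(path) -> pd.DataFrame:
    """Read a birth-record CSV and validate the required columns."""
    records = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    _validate_records(records)
    return records


def _validate_records(records: pd.DataFrame) -> None:
    if (records["weight"] <= 0).any():
        raise ValueError("sampling weights must be positive")
    if not records["death"].isin([0, 1]).all():
        raise ValueError("death indicator must be 0/1")


@dataclass
class ArealPanel:
    """Unit x period panel of weighted counts, exposures and covariates.

    Y, N, E are (I, T) float arrays; X is (I, T, p).  E is None until
    computed by :func:`expected_counts` or supplied by a simulation design.
    """

    unit_ids: list[str]
    periods: list[str]
    Y: np.ndarray
    N: np.ndarray
    E: np.ndarray | None = None
    X: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        I, T = len(self.unit_ids), len(self.periods)
        self.Y = np.asarray(self.Y, dtype=float).reshape(I, T)
        self.N = np.asarray(self.N, dtype=float).reshape(I, T)
        if (self.Y < 0).any():
            raise ValueError("negative death counts")
        if (self.N < self.Y).any():
            raise ValueError("births at risk N must be >= deaths Y in every cell")
        if self.E is not None:
            self.E = np.asarray(self.E, dtype=float).reshape(I, T)
            if (self.E < 0).any():
                raise ValueError("negative expected counts")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.shape != (I, T, len(self.covariate_names)):
                raise ValueError("X must have shape (I, T, p) matching covariate_names")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.unit_ids), len(self.periods)

    def validate(self, standardized: bool = False) -> None:
        """Invariant check; standardized=True additionally asserts sum E = sum Y."""
        if standardized:
            if self.E is None:
                raise ValueError("no expected counts present")
            total_y, total_e = self.Y.sum(), self.E.sum()
            if not np.isclose(total_e, total_y, rtol=1e-9):
                raise ValueError(
                    f"expected counts not internally standardized: "
                    f"sum E = {total_e}, sum Y = {total_y}"
                )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (unit, period)."""
        I, T = self.shape
        rows = {
            "unit_id": np.repeat(self.unit_ids, T),
            "period": np.tile(self.periods, I),
            "Y": self.Y.ravel(),
            "N": self.N.ravel(),
        }
        if self.E is not None:
            rows["E"] = self.E.ravel()
        for k, name in enumerate(self.covariate_names):
            rows[name] = self.X[:, :, k].ravel()
        return pd.DataFrame(rows)

    def replace(self, **kw) -> "ArealPanel":
        args = dict(
            unit_ids=list(self.unit_ids),
            periods=list(self.periods),
            Y=self.Y.copy(),
            N=self.N.copy(),
            E=None if self.E is None else self.E.copy(),
            X=None if self.X is None else self.X.copy(),
            covariate_names=list(self.covariate_names),
        )
        args.update(kw)
        return ArealPanel(**args)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def aggregate(
    records: pd.DataFrame,
    unit_ids: list[str],
    periods: list[str],
    covariate_rules: dict[str, str] | None = None,
) -> ArealPanel:
    """Aggregate birth records into an ArealPanel.

    Y_it = sum of weight*death, N_it = sum of weight over matching records.
    Covariates aggregate per declared rule: ``"sum"`` (weighted count,
    sum w*x), ``"proportion"`` (weighted mean of an indicator), or
    ``"median"`` (weighted median).  Cells with no records are zero-filled
    with a warning.
    """
    _validate_records(records)
    covariate_rules = covariate_rules or {}
    unknown_units = set(records["unit_id"].astype(str)) - set(unit_ids)
    unknown_periods = set(records["period"].astype(str)) - set(map(str, periods))
    if unknown_units or unknown_periods:
        raise ValueError(
            f"records reference unknown units {sorted(unknown_units)} "
            f"/ periods {sorted(unknown_periods)}"
        )
    for cov in covariate_rules:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} not in record columns")

    I, T = len(unit_ids), len(periods)
    uidx = {str(u): i for i, u in enumerate(unit_ids)}
    pidx = {str(p): t for t, p in enumerate(periods)}
    gi = records["unit_id"].astype(str).map(uidx).to_numpy()
    gt = records["period"].astype(str).map(pidx).to_numpy()
    w = records["weight"].to_numpy(dtype=float)
    d = records["death"].to_numpy(dtype=float)
    flat = gi * T + gt

    Y = np.bincount(flat, weights=w * d, minlength=I * T).reshape(I, T)
    N = np.bincount(flat, weights=w, minlength=I * T).reshape(I, T)
    if (N == 0).any():
        n_empty = int((N == 0).sum())
        warnings.warn(f"{n_empty} empty unit-period cells zero-filled")

    names = list(covariate_rules)
    X = np.zeros((I, T, len(names)))
    for k, name in enumerate(names):
        rule = covariate_rules[name]
        x = records[name].to_numpy(dtype=float)
        if rule == "sum":
            X[:, :, k] = np.bincount(flat, weights=w * x, minlength=I * T).reshape(I, T)
        elif rule == "proportion":
            num = np.bincount(flat, weights=w * x, minlength=I * T).reshape(I, T)
            with np.errstate(invalid="ignore"):
                X[:, :, k] = np.where(N > 0, num / np.where(N == 0, 1, N), 0.0)
        elif rule == "median":
            for cell in range(I * T):
                sel = flat == cell
                if sel.any():
                    X[cell // T, cell % T, k] = _weighted_median(x[sel], w[sel])
        else:
            raise ValueError(f"unknown covariate rule {rule!r} for {name!r}")
    return ArealPanel(
        [str(u) for u in unit_ids],
        [str(p) for p in periods],
        Y,
        N,
        X=X if names else None,
        covariate_names=names,
    )


def expected_counts(panel: ArealPanel, per_period: bool = False) -> ArealPanel:
    """Internal standardization: E_it = N_it * (sum Y / sum N).

    With ``per_period=True`` the overall rate is computed within each period
    separately (conservation then holds period by period).
    """
    if panel.N.sum() <= 0:
        raise ValueError("cannot standardize: total births at risk is zero")
    if per_period:
        col_n = panel.N.sum(axis=0)
        if (col_n == 0).any():
            raise ValueError("per-period standardization with an all-zero period")
        rate = panel.Y.sum(axis=0) / col_n
        E = panel.N * rate[None, :]
    else:
        rate = panel.Y.sum() / panel.N.sum()
        E = panel.N * rate
    return panel.replace(E=E)


def smr(panel: ArealPanel) -> np.ndarray:
    """Standardized mortality ratio Y_it / E_it.

    Cells with E=0 and Y=0 are undefined and returned as NaN; E=0 with Y>0
    is an error (standardization cannot have assigned zero risk there).
    """
    if panel.E is None:
        raise ValueError("expected counts not computed; call expected_counts first")
    zero_e = panel.E == 0
    if (zero_e & (panel.Y > 0)).any():
        raise ValueError("cell with E=0 but Y>0: inconsistent standardization")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero_e, np.nan, panel.Y / np.where(zero_e, 1.0, panel.E))
    return out


def weighted_nmr(records: pd.DataFrame, period: str | None = None) -> float:
    """Weighted neonatal mortality rate per 1000 live births.

    ``period=None`` pools all records (the combined crude rate); otherwise
    the rate is computed within the given survey period.
    """
    sub = records if period is None else records[records["period"].astype(str) == str(period)]
    if len(sub) == 0:
        raise ValueError(f"no records in scope (period={period!r})")
    w = sub["weight"].to_numpy(dtype=float)
    d = sub["death"].to_numpy(dtype=float)
    return float(1000.0 * (w * d).sum() / w.sum())


def indicator_table(records: pd.DataFrame, panel: ArealPanel) -> pd.DataFrame:
    """Per-period summary indicators plus the pooled crude rate.

    Columns: weighted SMR (sum Y / sum E within period), weighted NMR per
    1000 live births, and weighted relative risk (unweighted mean of
    unit-level SMRs, giving each areal unit equal weight).  A final row
    carries the pooled (all periods combined) weighted crude NMR.
    """
    if panel.E is None:
        raise ValueError("expected counts not computed")
    ratios = smr(panel)
    rows = []
    for t, period in enumerate(panel.periods):
        col_e = panel.E[:, t].sum()
        period_smr = panel.Y[:, t].sum() / col_e if col_e > 0 else np.nan
        unit_smrs = ratios[:, t]
        rows.append(
            {
                "period": period,
                "weighted_smr": period_smr,
                "weighted_nmr_per_1000": weighted_nmr(records, period),
                "weighted_rr": float(np.nanmean(unit_smrs)),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["combined_weighted_crude_nmr_per_1000"] = weighted_nmr(records)
    return table


def vif_screen(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[list[str], list[dict]]:
    """Iterative variance-inflation-factor screen for collinear covariates.

    Repeatedly drops the covariate with the largest VIF while that VIF
    exceeds ``threshold``; VIF_j = 1/(1 - R^2_j) from the OLS regression of
    column j on the remaining columns (with intercept).  Constant columns
    are dropped first with a warning.  Returns the surviving names in their
    original order and a log of drops.
    """
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than covariates for the VIF screen")
    names = list(X.columns)
    dropped: list[dict] = []
    for name in list(names):
        if np.ptp(X[name].to_numpy(dtype=float)) == 0:
            warnings.warn(f"constant covariate {name!r} dropped before VIF screen")
            names.remove(name)
            dropped.append({"name": name, "vif": np.inf, "reason": "constant"})
    while len(names) >= 2:
        vifs = _vifs(X[names].to_numpy(dtype=float))
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        dropped.append({"name": names[worst], "vif": float(vifs[worst]), "reason": "collinear"})
        del names[worst]
    return names, dropped


def _vifs(mat: np.ndarray) -> np.ndarray:
    n, p = mat.shape
    out = np.empty(p)
    intercept = np.ones((n, 1))
    for j in range(p):
        y = mat[:, j]
        others = np.hstack([intercept, np.delete(mat, j, axis=1)])
        resid = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out
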