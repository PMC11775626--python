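"""Collinearity screening of site covariates.

Two-phase stepwise removal before occupancy modelling: first any pair of
covariates with |Pearson r| above a cutoff (default 0.7) loses its less
preferred member, then covariates with variance inflation factor above a
cutoff (default 5) are removed one at a time.  A ``keep`` list encodes the
analyst's ecological preference: kept covariates are never dropped; if the
kept set itself violates a threshold, the violation is reported as a
warning but the keep preference is honoured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ScreenResult", "vif", "screen"]


@dataclass
class ScreenResult:
    retained: list
    dropped: list                 # (column, reason) pairs, in drop order
    correlation: pd.DataFrame
    final_vif: pd.Series
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "dropped": [{"column": c, "reason": r} for c, r in self.dropped],
            "final_vif": {k: float(v) for k, v in self.final_vif.items()},
            "warnings": list(self.warnings),
        }


def vif(df: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_k = 1 / (1 - R^2_k).

    R^2_k comes from the least-squares regression of column k on the other
    columns plus an intercept.  A single remaining column has VIF 1.
    """
    cols = list(df.columns)
    out = {}
    X = df.to_numpy(dtype=float)
    for k, c in enumerate(cols):
        ykk = X[:, k]
        others = np.delete(X, k, axis=1)
        if others.shape[1] == 0:
            out[c] = 1.0
            continue
        A = np.column_stack([np.ones(len(ykk)), others])
        coef, *_ = np.linalg.lstsq(A, ykk, rcond=None)
        resid = ykk - A @ coef
        ss_tot = np.sum((ykk - ykk.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        out[c] = 1.0 / max(1.0 - r2, 1e-300)
    return pd.Series(out, name="VIF")


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=0)


def screen(design: pd.DataFrame, r_threshold: float = 0.7,
           vif_threshold: float = 5.0, keep=()) -> ScreenResult:
    """Stepwise collinearity screen.

    Phase 1: while some retained pair has |r| > ``r_threshold``, drop the
    non-kept member of the worst pair with the larger VIF.  Phase 2: while
    the largest VIF among non-kept retained columns exceeds
    ``vif_threshold``, drop it.  Deterministic given column order and the
    keep list; idempotent on its own output.
    """
    cols = [c for c in design.columns]
    num = design[cols].astype(float)
    if num.shape[1] < 2:
        raise ValueError("screening needs at least 2 numeric columns")
    sd = num.std(ddof=0)
    constant = list(sd.index[sd == 0.0])
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    keep = [k for k in keep]
    unknown = set(keep) - set(cols)
    if unknown:
        raise KeyError(f"keep columns not in design: {sorted(unknown)}")

    Z = _standardize(num)
    corr = Z.corr()
    retained = list(cols)
    dropped: list = []
    warns: list = []

    def worst_pair(cs):
        best = None
        for i, a in enumerate(cs):
            for b in cs[i + 1 :]:
                r = abs(corr.loc[a, b])
                if r > r_threshold and (best is None or r > best[0]):
                    best = (r, a, b)
        return best

    # phase 1: pairwise correlation rule
    while True:
        hit = worst_pair(retained)
        if hit is None:
            break
        r, a, b = hit
        in_keep = (a in keep, b in keep)
        if all(in_keep):
            msg = (f"kept covariates {a!r} and {b!r} correlated "
                   f"|r|={r:.3f} > {r_threshold}; keep honoured")
            if msg not in warns:
                warns.append(msg)
                warnings.warn(msg)
            # keep-set violation: cannot drop either; stop revisiting the pair
            corr.loc[a, b] = corr.loc[b, a] = 0.0
            continue
        if in_keep[0]:
            victim = b
        elif in_keep[1]:
            victim = a
        else:
            v = vif(Z[retained])
            victim = a if v[a] > v[b] else b
        retained.remove(victim)
        dropped.append((victim, f"|r|={r:.3f} with "
                                f"{a if victim == b else b} > {r_threshold}"))

    # phase 2: VIF rule
    while len(retained) >= 2:
        v = vif(Z[retained])
        cand = v.drop(index=[c for c in keep if c in v.index], errors="ignore")
        if (v > vif_threshold).any() and cand.empty:
            msg = (f"kept covariates exceed VIF threshold "
                   f"(max VIF {v.max():.2f} > {vif_threshold}); keep honoured")
            warns.append(msg)
            warnings.warn(msg)
            break
        if cand.empty or cand.max() <= vif_threshold:
            kept_bad = v[(v > vif_threshold) & v.index.isin(keep)]
            for c, val in kept_bad.items():
                msg = f"kept covariate {c!r} has VIF {val:.2f} > {vif_threshold}"
                if msg not in warns:
                    warns.append(msg)
                    warnings.warn(msg)
            break
        victim = cand.idxmax()
        dropped.append((victim, f"VIF={cand.max():.3f} > {vif_threshold}"))
        retained.remove(victim)

    final = vif(Z[retained]) if len(retained) >= 2 else pd.Series(
        {retained[0]: 1.0} if retained else {}, name="VIF")
    return ScreenResult(retained=retained, dropped=dropped,
                        correlation=_standardize(num).corr(),
                        final_vif=final, warnings=warns)
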