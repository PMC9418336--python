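"""Design-based accuracy assessment and unbiased area estimation.

Follows the stratified good-practice estimators for map accuracy: strata
are the mapped classes with weights W_i (mapped proportions); reference
counts n_ij convert to area-weighted cell proportions

    p_ij = W_i * n_ij / n_i.

from which overall accuracy OA = sum_i p_ii, user's accuracy
UA_i = p_ii / p_i., producer's accuracy PA_j = p_jj / p._j, and the
error-adjusted area share of class j is the column total p._j. Standard
errors use the stratified variance estimators:

    V(UA_i) = UA_i (1 - UA_i) / (n_i. - 1)
    V(OA)   = sum_i W_i^2 UA_i (1 - UA_i) / (n_i. - 1)
    V(p._j) = sum_i W_i^2 q_ij (1 - q_ij) / (n_i. - 1),  q_ij = n_ij / n_i.
    V(PA_j) combines commission of class j with omission into class j.

95% intervals are normal-approximation (1.96 SE). A published matrix of
proportions can be ingested directly; point estimates then reproduce the
printed arithmetic exactly (no CIs without counts).

The sample-size formula for a target standard error of OA under assumed
user's accuracies is n = ( sum_i W_i S_i / SE_target )^2 with
S_i = sqrt(UA_i (1 - UA_i)); allocation places a fixed floor per class
and distributes the remainder proportionally to the weights by largest
remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ClassMap

Z95 = 1.96


def sample_size(weights, ua_assumed, se_target: float) -> int:
    """Stratified sample size for a target SE of overall accuracy.

    ``n = round((sum_i W_i sqrt(UA_i (1-UA_i)) / SE)^2)``; when all
    assumed user's accuracies are equal the result is independent of the
    weights (they sum to 1).
    """
    w = np.asarray(weights, dtype=np.float64)
    ua = np.broadcast_to(np.asarray(ua_assumed, dtype=np.float64), w.shape)
    if not np.isclose(w.sum(), 1.0, atol=1e-6):
        raise ValueError("stratum weights must sum to 1")
    if se_target <= 0:
        raise ValueError("target standard error must be positive")
    s = np.sqrt(ua * (1.0 - ua))
    return int(round(((w * s).sum() / se_target) ** 2))


def allocate(n: int, weights, per_class_floor: int = 200) -> np.ndarray:
    """Floor-plus-proportional allocation of n samples over strata.

    Each stratum receives the floor; the remainder is split proportionally
    to the weights with largest-remainder rounding so the total is exact.
    """
    w = np.asarray(weights, dtype=np.float64)
    k = w.size
    if n < k * per_class_floor:
        raise ValueError(
            f"n={n} cannot cover a floor of {per_class_floor} for {k} classes")
    remainder = n - k * per_class_floor
    quota = remainder * w / w.sum()
    base = np.floor(quota).astype(int)
    short = remainder - base.sum()
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    base[order[:short]] += 1
    return per_class_floor + base


def draw_validation_sample(class_map: ClassMap, allocation: dict[int, int],
                           seed: int = 0) -> pd.DataFrame:
    """Stratified simple random sample (without replacement) of pixels.

    Returns a frame with row, col and the mapped stratum code; reference
    labeling happens downstream (an ``unlabelable`` response may later be
    excluded from the matrix without touching the design weights).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for code, n_i in sorted(allocation.items()):
        rs, cs = np.nonzero(class_map.codes == code)
        if rs.size < n_i:
            raise ValueError(
                f"stratum {code} has only {rs.size} pixels for {n_i} samples")
        sel = rng.choice(rs.size, size=n_i, replace=False)
        frames.append(pd.DataFrame({
            "row": rs[sel], "col": cs[sel], "map_class": code,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class ErrorMatrixEstimate:
    """Area-weighted error matrix and its derived estimators.

    Rows index map (stratum) classes, columns reference classes. ``p`` is
    the matrix of area-weighted cell proportions; ``counts``/``n_i`` are
    retained when the estimate came from raw counts, enabling variance
    estimation.
    """

    p: np.ndarray
    weights: np.ndarray
    class_codes: np.ndarray
    counts: np.ndarray | None = None
    n_i: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.class_codes = np.asarray(self.class_codes)
        k = self.p.shape[0]
        if self.p.shape != (k, k):
            raise ValueError("error matrix must be square")
        total = self.p.sum()
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"cell proportions sum to {total:.4f}, expected 1 (±1e-3)")

    # -- point estimates ---------------------------------------------------
    @property
    def k(self) -> int:
        return self.p.shape[0]

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.p))

    @property
    def users_accuracy(self) -> np.ndarray:
        rows = self.p.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rows > 0, np.diag(self.p) / rows, np.nan)

    @property
    def producers_accuracy(self) -> np.ndarray:
        cols = self.p.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cols > 0, np.diag(self.p) / cols, np.nan)

    @property
    def area_shares(self) -> np.ndarray:
        """Error-adjusted area share per class (column totals)."""
        return self.p.sum(axis=0)

    # -- uncertainties (counts mode only) ----------------------------------
    def _require_counts(self):
        if self.counts is None or self.n_i is None:
            raise ValueError("confidence intervals require raw counts")

    def se_users_accuracy(self) -> np.ndarray:
        self._require_counts()
        ua = self.users_accuracy
        denom = self.n_i - 1
        out = np.full(self.k, np.nan)
        ok = denom > 0
        out[ok] = np.sqrt(ua[ok] * (1 - ua[ok]) / denom[ok])
        return out

    def se_overall_accuracy(self) -> float:
        self._require_counts()
        ua = self.users_accuracy
        denom = self.n_i - 1
        ok = denom > 0
        var = np.sum(self.weights[ok] ** 2 * ua[ok] * (1 - ua[ok]) / denom[ok])
        return float(np.sqrt(var))

    def se_area_shares(self) -> np.ndarray:
        self._require_counts()
        q = self.counts / self.n_i[:, None]
        denom = (self.n_i - 1)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(denom > 0,
                           (self.weights[:, None] ** 2) * q * (1 - q) / denom,
                           np.nan)
        return np.sqrt(np.nansum(var, axis=0))

    def se_producers_accuracy(self) -> np.ndarray:
        self._require_counts()
        pa = self.producers_accuracy
        ua = self.users_accuracy
        q = self.counts / self.n_i[:, None]
        col = self.area_shares
        out = np.full(self.k, np.nan)
        for j in range(self.k):
            if not np.isfinite(pa[j]) or col[j] <= 0 or self.n_i[j] <= 1:
                continue
            term1 = (self.weights[j] ** 2 * (1 - pa[j]) ** 2
                     * ua[j] * (1 - ua[j]) / (self.n_i[j] - 1))
            term2 = 0.0
            for i in range(self.k):
                if i == j or self.n_i[i] <= 1:
                    continue
                term2 += (self.weights[i] ** 2 * q[i, j] * (1 - q[i, j])
                          / (self.n_i[i] - 1))
            out[j] = np.sqrt((term1 + pa[j] ** 2 * term2) / col[j] ** 2)
        return out

    def has_counts(self) -> bool:
        return self.counts is not None

    def summary(self) -> pd.DataFrame:
        data = {
            "class_code": self.class_codes,
            "users_accuracy": self.users_accuracy,
            "producers_accuracy": self.producers_accuracy,
            "area_share": self.area_shares,
        }
        if self.has_counts():
            data["ua_ci95"] = Z95 * self.se_users_accuracy()
            data["pa_ci95"] = Z95 * self.se_producers_accuracy()
            data["area_ci95"] = Z95 * self.se_area_shares()
        return pd.DataFrame(data)


def error_matrix_from_counts(counts, weights, class_codes=None
                             ) -> ErrorMatrixEstimate:
    """Estimate from raw reference counts n_ij and stratum weights W_i."""
    counts = np.asarray(counts, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    k = counts.shape[0]
    if counts.shape != (k, k):
        raise ValueError("counts matrix must be square")
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("stratum weights must sum to 1")
    n_i = counts.sum(axis=1)
    if np.any(n_i == 0):
        raise ValueError("every stratum needs at least one reference sample")
    p = weights[:, None] * counts / n_i[:, None]
    codes = np.arange(1, k + 1) if class_codes is None else np.asarray(class_codes)
    return ErrorMatrixEstimate(p, weights, codes, counts=counts, n_i=n_i)


def error_matrix_from_proportions(p, class_codes=None, renormalize=False
                                  ) -> ErrorMatrixEstimate:
    """Ingest a published matrix of area-weighted proportions directly.

    Point estimates only. Published rounding may leave the cell sum within
    ±1e-3 of 1; by default the raw arithmetic is reported so printed
    figures reproduce as printed, ``renormalize=True`` rescales to an
    exact unit sum.
    """
    p = np.asarray(p, dtype=np.float64)
    if renormalize:
        p = p / p.sum()
    k = p.shape[0]
    codes = np.arange(1, k + 1) if class_codes is None else np.asarray(class_codes)
    return ErrorMatrixEstimate(p, p.sum(axis=1), codes)


def merge_classes(est: ErrorMatrixEstimate, mapping: dict) -> ErrorMatrixEstimate:
    """Aggregate an estimate under a class mapping (old code -> new code).

    Cells, strata weights and (when present) counts are summed over the
    merged groups; merging can only move mass onto the diagonal, so
    overall accuracy never decreases.
    """
    old = list(est.class_codes)
    new_codes = sorted(set(mapping[c] for c in old))
    idx = {c: new_codes.index(mapping[c]) for c in old}
    k_new = len(new_codes)
    p = np.zeros((k_new, k_new))
    counts = np.zeros((k_new, k_new)) if est.has_counts() else None
    w = np.zeros(k_new)
    for i, ci in enumerate(old):
        w[idx[ci]] += est.weights[i]
        for j, cj in enumerate(old):
            p[idx[ci], idx[cj]] += est.p[i, j]
            if counts is not None:
                counts[idx[ci], idx[cj]] += est.counts[i, j]
    n_i = counts.sum(axis=1) if counts is not None else None
    return ErrorMatrixEstimate(p, w, np.asarray(new_codes), counts=counts,
                               n_i=n_i)


def area_report(est: ErrorMatrixEstimate, class_names=None) -> pd.DataFrame:
    """Per-class error-adjusted area shares (with 95% CIs in counts mode)."""
    df = pd.DataFrame({
        "class_code": est.class_codes,
        "area_share": est.area_shares,
    })
    if est.has_counts():
        df["area_ci95"] = Z95 * est.se_area_shares()
    if class_names:
        df.insert(1, "class_name",
                  [class_names.get(int(c), str(c)) for c in est.class_codes])
    return df
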