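"""Between-group statistics for spectral feature matrices.

Nonparametric two-sample permutation t-tests (10,000 permutations by default,
exhaustive enumeration when the number of distinct label assignments is
small), Benjamini–Hochberg FDR control across the signals x features family,
post hoc Pearson correlations, and a lateralization index over homologous
left/right signal pairs.

The comparison stage is exposed statsmodels-style: build a
:class:`GroupContrast` model from a :class:`FeatureMatrix`, call ``fit`` and
read the :class:`PermTestResult` it returns (``summary()``, ``to_frame()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidArgumentError, UndefinedStatisticError
from .spectral import FEATURE_NAMES, SpectralFeatures

__all__ = [
    "FeatureMatrix",
    "PermutationTTest",
    "PermTestResult",
    "CorrelationResult",
    "permutation_ttest",
    "fdr_correct",
    "group_compare",
    "GroupContrast",
    "pearson_correlation",
    "lateralization_index",
    "lateralization_table",
]


# ---------------------------------------------------------------------------
# Containers


@dataclass
class FeatureMatrix:
    """Subjects x signals x features array with group labels and covariates."""

    values: np.ndarray
    feature_names: Sequence[str]
    subject_table: pd.DataFrame
    signal_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidArgumentError("values must be (subjects x signals x features)")
        n_s, n_sig, n_f = self.values.shape
        if len(self.subject_table) != n_s:
            raise InvalidArgumentError("subject_table rows must match subjects")
        if "group" not in self.subject_table.columns or self.subject_table["group"].isna().any():
            raise InvalidArgumentError("subject_table must have a complete 'group' column")
        if len(self.feature_names) != n_f:
            raise InvalidArgumentError("feature_names must match the feature axis")
        if len(self.signal_meta) != n_sig:
            raise InvalidArgumentError("signal_meta rows must match signals")
        self.feature_names = list(self.feature_names)

    @classmethod
    def from_features(
        cls, features: Sequence[SpectralFeatures], subject_table: pd.DataFrame
    ) -> "FeatureMatrix":
        """Stack per-subject :class:`SpectralFeatures` into a matrix."""
        if not features:
            raise InvalidArgumentError("no feature sets supplied")
        values = np.stack(
            [np.column_stack([f[name] for name in FEATURE_NAMES]) for f in features]
        )
        return cls(
            values=values,
            feature_names=list(FEATURE_NAMES),
            subject_table=subject_table.reset_index(drop=True),
            signal_meta=features[0].signal_meta.reset_index(drop=True),
        )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def groups(self) -> list[str]:
        return sorted(self.subject_table["group"].unique())

    def group_values(self, group: str) -> np.ndarray:
        mask = (self.subject_table["group"] == group).to_numpy()
        return self.values[mask]

    def signal_labels(self) -> list[str]:
        for col in ("label", "name"):
            if col in self.signal_meta.columns:
                return list(self.signal_meta[col])
        return [f"signal{i + 1:03d}" for i in range(self.values.shape[1])]


@dataclass
class PermutationTTest:
    """Observed t and permutation p for one call (scalar or vector-valued)."""

    t: np.ndarray | float
    p: np.ndarray | float
    exhaustive: bool
    n_permutations: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Permutation machinery


def _group_t(data: np.ndarray, masks: np.ndarray, n_a: int, n_b: int, equal_var: bool) -> np.ndarray:
    """Two-sample t statistics for many label assignments at once.

    ``data`` is (n, k); ``masks`` is (m, n) with 1.0 marking group-a members.
    Returns (m, k) statistics, t = mean_a - mean_b over its standard error.
    """
    n = n_a + n_b
    data2 = data * data
    s_all = data.sum(axis=0)
    q_all = data2.sum(axis=0)
    sa = masks @ data
    qa = masks @ data2
    sb = s_all - sa
    qb = q_all - qa
    ma = sa / n_a
    mb = sb / n_b
    ssa = np.maximum(qa - sa * sa / n_a, 0.0)
    ssb = np.maximum(qb - sb * sb / n_b, 0.0)
    if equal_var:
        sp2 = (ssa + ssb) / (n - 2)
        denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        denom = np.sqrt(ssa / (n_a - 1) / n_a + ssb / (n_b - 1) / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(np.isfinite(t), t, 0.0)


def _exhaustive_masks(n: int, n_a: int) -> np.ndarray:
    idx = np.fromiter(
        (i for combo in combinations(range(n), n_a) for i in combo), dtype=np.intp
    ).reshape(-1, n_a)
    masks = np.zeros((idx.shape[0], n), dtype=float)
    np.put_along_axis(masks, idx, 1.0, axis=1)
    return masks


def _sampled_masks(rng: np.random.Generator, n: int, n_a: int, n_perm: int) -> np.ndarray:
    base = np.zeros(n, dtype=float)
    base[:n_a] = 1.0
    masks = np.tile(base, (n_perm, 1))
    return rng.permuted(masks, axis=1)


def permutation_ttest(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
    equal_var: bool = True,
) -> PermutationTTest:
    """Two-tailed two-sample permutation t-test.

    ``a`` and ``b`` are (n_a,) or (n_a, k) arrays (columns tested jointly
    under one shared permutation schedule).  When the number of distinct
    label assignments C(n, n_a) does not exceed ``n_perm`` the null
    distribution is enumerated exhaustively and ``p`` is the exact fraction
    of assignments (identity included) with ``|t*| >= |t_obs|``; otherwise
    ``n_perm`` random assignments are drawn and the add-one convention
    ``p = (1 + #{|t*| >= |t_obs|}) / (1 + n_perm)`` keeps p strictly positive.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    scalar = a.ndim == 1
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise InvalidArgumentError("each group needs at least 2 observations")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    data = np.vstack([a, b])
    n = n_a + n_b

    obs_mask = np.zeros((1, n))
    obs_mask[0, :n_a] = 1.0
    t_obs = _group_t(data, obs_mask, n_a, n_b, equal_var)[0]
    if np.any(a.var(axis=0) + b.var(axis=0) <= 0):
        raise UndefinedStatisticError("zero pooled within-group variance: t statistic undefined")

    total = comb(n, n_a)
    tol = 1e-10 * (1.0 + np.abs(t_obs))
    if total <= n_perm:
        masks = _exhaustive_masks(n, n_a)
        t_null = _group_t(data, masks, n_a, n_b, equal_var)
        count = (np.abs(t_null) >= np.abs(t_obs)[None, :] - tol).sum(axis=0)
        p = count / total
        result = PermutationTTest(t=t_obs, p=p, exhaustive=True, n_permutations=total)
    else:
        rng = np.random.default_rng(seed)
        masks = _sampled_masks(rng, n, n_a, n_perm)
        t_null = _group_t(data, masks, n_a, n_b, equal_var)
        count = (np.abs(t_null) >= np.abs(t_obs)[None, :] - tol).sum(axis=0)
        p = (1.0 + count) / (1.0 + n_perm)
        result = PermutationTTest(t=t_obs, p=p, exhaustive=False, n_permutations=n_perm)
    if scalar:
        result.t = float(result.t[0])
        result.p = float(result.p[0])
    return result


def fdr_correct(p, level: float = 0.05):
    """Benjamini–Hochberg step-up over the supplied family.

    ``p`` may be any shape; the family is the flattened array.  Returns
    ``(q, rejected)`` with the input shape, where ``q`` are BH-adjusted
    p-values and ``rejected = q <= level``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in (0, 1]")
    _, q_flat, _, _ = multipletests(p.ravel(), alpha=level, method="fdr_bh")
    q = q_flat.reshape(p.shape)
    return q, q <= level


# ---------------------------------------------------------------------------
# Model-style group comparison


@dataclass
class PermTestResult:
    """Results of a signals x features permutation contrast.

    ``t_obs``, ``p_perm``, ``q_fdr`` and ``rejected`` are DataFrames indexed
    by signal with one column per feature; ``groups`` is the ``(a, b)`` label
    pair with ``t = mean_a - mean_b``.
    """

    t_obs: pd.DataFrame
    p_perm: pd.DataFrame
    q_fdr: pd.DataFrame
    rejected: pd.DataFrame
    n_permutations: int
    exhaustive: bool
    seed: int | None
    level: float
    fdr_family: str
    groups: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per signal x feature."""
        rows = []
        for feature in self.t_obs.columns:
            for signal in self.t_obs.index:
                rows.append(
                    {
                        "signal_id": signal,
                        "feature": feature,
                        "t": self.t_obs.at[signal, feature],
                        "p": self.p_perm.at[signal, feature],
                        "q": self.q_fdr.at[signal, feature],
                        "rejected": bool(self.rejected.at[signal, feature]),
                    }
                )
        return pd.DataFrame(rows)

    def n_rejected(self) -> int:
        return int(self.rejected.to_numpy().sum())

    def summary(self) -> str:
        a, b = self.groups
        m = self.t_obs.size
        lines = [
            "Permutation group contrast",
            "==========================",
            f"contrast:        {a} - {b}",
            f"family:          {self.t_obs.shape[0]} signals x {self.t_obs.shape[1]} features"
            f" (FDR: {self.fdr_family}, m = {m})",
            f"permutations:    {self.n_permutations}"
            + (" (exhaustive)" if self.exhaustive else f" (sampled, seed={self.seed})"),
            f"level:           {self.level}",
            f"rejected:        {self.n_rejected()} / {m}",
            "",
        ]
        rej = self.to_frame().query("rejected").sort_values("q")
        if len(rej):
            lines.append("significant signal x feature pairs (by q):")
            lines.append(rej.head(25).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
            if len(rej) > 25:
                lines.append(f"... and {len(rej) - 25} more")
        else:
            lines.append("no significant pairs at the given level")
        return "\n".join(lines)


def group_compare(
    fm: FeatureMatrix,
    n_permutations: int = 10000,
    seed: int | None = None,
    level: float = 0.05,
    fdr_family: str = "joint",
    groups: tuple[str, str] | None = None,
    equal_var: bool = True,
) -> PermTestResult:
    """Permutation t-tests per signal x feature with a shared permutation
    schedule, followed by joint (or per-feature) BH correction.

    ``groups=(a, b)`` sets the contrast direction ``t = mean_a - mean_b``;
    the default is ``("patient", "control")`` when both labels are present,
    otherwise the two labels in sorted order.
    """
    labels = fm.groups
    if len(labels) != 2:
        raise InvalidArgumentError(f"exactly two groups required, found {labels}")
    if groups is None:
        groups = ("patient", "control") if set(labels) == {"patient", "control"} else tuple(labels)
    g_a, g_b = groups
    a = fm.group_values(g_a)
    b = fm.group_values(g_b)
    n_sig, n_feat = fm.values.shape[1], fm.values.shape[2]
    res = permutation_ttest(
        a.reshape(a.shape[0], -1),
        b.reshape(b.shape[0], -1),
        n_perm=n_permutations,
        seed=seed,
        equal_var=equal_var,
    )
    t = np.asarray(res.t).reshape(n_sig, n_feat)
    p = np.asarray(res.p).reshape(n_sig, n_feat)
    if fdr_family == "joint":
        q, rej = fdr_correct(p, level)
    elif fdr_family == "per_feature":
        q = np.empty_like(p)
        rej = np.empty_like(p, dtype=bool)
        for j in range(n_feat):
            q[:, j], rej[:, j] = fdr_correct(p[:, j], level)
    else:
        raise InvalidArgumentError("fdr_family must be 'joint' or 'per_feature'")
    index = pd.Index(fm.signal_labels(), name="signal_id")
    cols = fm.feature_names
    return PermTestResult(
        t_obs=pd.DataFrame(t, index=index, columns=cols),
        p_perm=pd.DataFrame(p, index=index, columns=cols),
        q_fdr=pd.DataFrame(q, index=index, columns=cols),
        rejected=pd.DataFrame(rej, index=index, columns=cols),
        n_permutations=res.n_permutations,
        exhaustive=res.exhaustive,
        seed=seed,
        level=level,
        fdr_family=fdr_family,
        groups=groups,
    )


class GroupContrast:
    """Model object for the signals x features group contrast.

    Parameters mirror :func:`group_compare`; ``fit(seed=...)`` runs the
    permutation schedule and returns a :class:`PermTestResult`.
    """

    def __init__(
        self,
        feature_matrix: FeatureMatrix,
        n_permutations: int = 10000,
        level: float = 0.05,
        fdr_family: str = "joint",
        groups: tuple[str, str] | None = None,
        equal_var: bool = True,
    ):
        self.feature_matrix = feature_matrix
        self.n_permutations = n_permutations
        self.level = level
        self.fdr_family = fdr_family
        self.groups = groups
        self.equal_var = equal_var

    @classmethod
    def from_features(
        cls, features: Sequence[SpectralFeatures], subject_table: pd.DataFrame, **kwargs
    ) -> "GroupContrast":
        return cls(FeatureMatrix.from_features(features, subject_table), **kwargs)

    def fit(self, seed: int | None = None) -> PermTestResult:
        return group_compare(
            self.feature_matrix,
            n_permutations=self.n_permutations,
            seed=seed,
            level=self.level,
            fdr_family=self.fdr_family,
            groups=self.groups,
            equal_var=self.equal_var,
        )


# ---------------------------------------------------------------------------
# Post hoc analyses


def pearson_correlation(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p-value.

    Pairs with missing values are dropped (never imputed) and the retained n
    is reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InvalidArgumentError(f"need at least 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def lateralization_index(left, right):
    """LI = (left - right) / (left + right); requires positive inputs.

    Antisymmetric under swapping sides and bounded in (-1, 1).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise InvalidArgumentError("lateralization index requires positive inputs")
    li = (left - right) / (left + right)
    return float(li) if li.ndim == 0 else li


def lateralization_table(fm: FeatureMatrix, feature: str = "alpha_power_ratio") -> pd.DataFrame:
    """Per-subject LI for every homologous L/R signal pair.

    Pairs come from the ``pair`` and ``hemisphere`` columns of the signal
    metadata; rows are (subject_id, pair, group, li).
    """
    meta = fm.signal_meta
    if "pair" not in meta.columns or "hemisphere" not in meta.columns:
        raise InvalidArgumentError("signal_meta needs 'pair' and 'hemisphere' columns")
    j = fm.feature_names.index(feature)
    rows = []
    for pair_id, grp in meta.groupby("pair"):
        if pair_id < 0:
            continue
        hemis = set(grp["hemisphere"])
        if not {"L", "R"} <= hemis:
            continue
        li_idx = grp.index[grp["hemisphere"] == "L"][0]
        ri_idx = grp.index[grp["hemisphere"] == "R"][0]
        left = fm.values[:, li_idx, j]
        right = fm.values[:, ri_idx, j]
        li = lateralization_index(left, right)
        for s in range(fm.n_subjects):
            rows.append(
                {
                    "subject_id": fm.subject_table["subject_id"].iloc[s]
                    if "subject_id" in fm.subject_table.columns
                    else s,
                    "group": fm.subject_table["group"].iloc[s],
                    "pair": int(pair_id),
                    "li": float(li[s]),
                }
            )
    return pd.DataFrame(rows)
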