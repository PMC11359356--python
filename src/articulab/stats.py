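"""Non-parametric statistical battery ranking features by effect size.

Per feature the battery runs: a Shapiro-Wilk normality screen (recorded,
not gating — the analysis is non-parametric throughout), a log transform
for highly skewed features, a Brown-Forsythe variance-homogeneity test
(recorded) with a variance-ratio exclusion rule (any between-group ratio
above 10 or below 0.1 drops the feature), then a Mann-Whitney U test with
the rank-biserial correlation rb for two groups, or a Kruskal-Wallis test
with eta-squared plus Bonferroni-adjusted pairwise post hoc tests for
three.  Significant features (p < alpha) are reported sorted by effect
size, mirroring the study's result tables.

The model surface follows the usual statistical-modelling idiom: build an
:class:`ArticulationStudy` from a speaker-level feature table, call
``fit()`` and inspect the returned :class:`StudyResults`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst

from .containers import PipelineConfig
from .profiles import ALLOWED_CLASSES, coerce_sibilant

log = logging.getLogger("articulab")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# building blocks

def normality_screen(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value (descriptive; requires 3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if len(x) > 5000:
        raise ValueError("Shapiro-Wilk supports at most 5000 observations")
    if np.ptp(x) == 0:
        return 0.0
    return float(sst.shapiro(x).pvalue)


def maybe_log_transform(
    values: np.ndarray, skew_threshold: float = 2.0
) -> Tuple[np.ndarray, bool]:
    """Log-transform highly skewed data: ``log(x - min(x) + eps)`` when
    ``|skewness| > skew_threshold``, identity otherwise.

    The shift guarantees positivity; callers apply the same decision and
    shift to every group of a feature (transform pooled, then split).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return x, False
    skew = float(sst.skew(x))
    if not math.isfinite(skew) or abs(skew) <= skew_threshold:
        return x, False
    eps = 1e-6 * float(np.ptp(x))
    return np.log(x - float(np.min(x)) + eps), True


def brown_forsythe(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Median-centred Levene test of variance homogeneity: (W, p)."""
    if len(groups) < 2:
        raise ValueError("Brown-Forsythe needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    res = sst.levene(*groups, center="median")
    return float(res.statistic), float(res.pvalue)


def variance_ratio_screen(
    groups: Sequence[np.ndarray], bounds: Tuple[float, float] = (0.1, 10.0)
) -> Tuple[bool, float]:
    """Check every between-group variance ratio against ``bounds``.

    Returns ``(ok, worst_ratio)`` where the worst ratio is the most
    extreme pairwise ``var_i / var_j``.  Any zero-variance group fails the
    screen (ratio reported as inf).
    """
    variances = [float(np.var(np.asarray(g, dtype=float), ddof=1)) for g in groups]
    if any(v <= _EPS for v in variances):
        return False, float("inf")
    worst = 1.0
    ok = True
    for vi, vj in itertools.permutations(variances, 2):
        ratio = vi / vj
        if abs(math.log(ratio)) > abs(math.log(worst)):
            worst = ratio
        if not bounds[0] <= ratio <= bounds[1]:
            ok = False
    return ok, worst


def mann_whitney_rb(
    g1: np.ndarray, g2: np.ndarray
) -> Tuple[float, float, float]:
    """Mann-Whitney U test with the rank-biserial effect size.

    U is the midrank statistic for the first group (the count of
    ``g1 > g2`` pairs plus half the ties); the two-sided p-value uses
    exact enumeration for small tie-free samples and the tie-corrected
    normal approximation with continuity correction otherwise.
    ``rb = |1 - 2U/(n1*n2)|``; direction is read off the group medians.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = sst.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    rb = abs(1.0 - 2.0 * u / (len(x) * len(y)))
    return u, float(res.pvalue), rb


def kruskal_eta2(groups: Sequence[np.ndarray]) -> Tuple[float, float, float]:
    """Tie-corrected Kruskal-Wallis H, chi-squared p and eta-squared.

    ``eta2 = (H - k + 1) / (n - k)``, reported at full precision (may be
    negative for very small H).
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    k = len(groups)
    n = sum(len(g) for g in groups)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:  # all observations identical: no evidence at all
        h = 0.0
        return h, 1.0, float((h - k + 1) / (n - k))
    res = sst.kruskal(*groups)
    h = float(res.statistic)
    eta2 = (h - k + 1) / (n - k)
    return h, float(res.pvalue), float(eta2)


def eta_squared_from_h(h: float, k: int, n: int) -> float:
    """eta-squared effect size from a Kruskal-Wallis H statistic."""
    return (h - k + 1) / (n - k)


def bonferroni_posthoc(
    groups: Sequence[np.ndarray], labels: Optional[Sequence[str]] = None
) -> Dict[str, float]:
    """Pairwise Mann-Whitney tests with Bonferroni adjustment (x3, capped
    at 1).  Pairs are labeled ``1-2, 1-3, 2-3`` in class order."""
    if len(groups) != 3:
        raise ValueError("post hoc analysis expects exactly 3 groups")
    m = len(groups) * (len(groups) - 1) // 2
    out: Dict[str, float] = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        _, p, _ = mann_whitney_rb(groups[i], groups[j])
        out[f"{i + 1}-{j + 1}"] = min(1.0, m * p)
    return out


_RB_BANDS = [(0.60, "high"), (0.40, "medium"), (0.10, "low")]
_ETA2_BANDS = [(0.14, "high"), (0.06, "medium"), (0.01, "low")]


def classify_effect(effect: float, test: str) -> str:
    """Effect-size band: rb thresholds 0.40/0.60 (|rb| < 0.10 negligible),
    eta2 thresholds 0.01/0.06/0.14."""
    bands = _RB_BANDS if test == "MW" else _ETA2_BANDS
    value = abs(effect) if test == "MW" else effect
    for floor, band in bands:
        if value >= floor:
            return band
    return "negligible"


# ---------------------------------------------------------------------------
# per-feature result

@dataclass
class TestResult:
    feature_name: str
    data_kind: str = ""
    category: str = ""
    camera: str = "none"
    test: str = ""
    statistic: float = float("nan")
    p: float = float("nan")
    effect: float = float("nan")
    effect_band: str = ""
    posthoc_p: Dict[str, float] = field(default_factory=dict)
    group_medians: Dict[str, float] = field(default_factory=dict)
    sw_p: Dict[str, float] = field(default_factory=dict)
    bf_p: float = float("nan")
    log_transformed: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


# ---------------------------------------------------------------------------
# the study model

class ArticulationStudy:
    """Non-parametric group-difference study over a speaker feature table.

    Parameters
    ----------
    data
        Speaker-level table: one row per speaker, an articulation-class
        column plus feature columns.
    sibilant
        Which sibilant the table describes; fixes the class order used
        for post hoc pair labels.
    feature_columns
        Feature columns to analyse (default: all non-id numeric columns).
    config
        Pipeline constants (alpha, variance-ratio bounds, skewness
        threshold).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        sibilant,
        feature_columns: Optional[Sequence[str]] = None,
        group_col: str = "articulation_class",
        config: Optional[PipelineConfig] = None,
    ):
        self.data = data.reset_index(drop=True)
        self.sibilant = coerce_sibilant(sibilant)
        self.group_col = group_col
        self.config = config or PipelineConfig()
        if group_col not in data.columns:
            raise ValueError(f"missing group column {group_col!r}")
        present = set(self.data[group_col].unique())
        self.class_order = [
            c.value for c in ALLOWED_CLASSES[self.sibilant] if c.value in present
        ]
        unknown = present - set(self.class_order)
        if unknown:
            raise ValueError(
                f"classes {sorted(unknown)} are not analysed for {self.sibilant.ipa}"
            )
        if len(self.class_order) < 2:
            raise ValueError("need at least 2 articulation classes")
        counts = self.data[group_col].value_counts()
        if (counts < 3).any():
            raise ValueError("each class needs at least 3 speakers")
        if feature_columns is None:
            skip = {group_col, "speaker_id", "sibilant"}
            feature_columns = [
                c
                for c in self.data.columns
                if c not in skip and pd.api.types.is_numeric_dtype(self.data[c])
            ]
        self.feature_columns = list(feature_columns)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, sibilant, **kwargs) -> "ArticulationStudy":
        return cls(data, sibilant, **kwargs)

    # -- fitting ------------------------------------------------------------

    def _analyse_feature(self, name: str, meta: Mapping[str, str]) -> TestResult:
        cfg = self.config
        res = TestResult(feature_name=name, **meta)
        pooled = self.data[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(pooled)):
            res.excluded = True
            res.exclusion_reason = "non-finite values"
            return res
        transformed, flag = maybe_log_transform(pooled, cfg.skew_threshold)
        res.log_transformed = flag
        groups = []
        for cls in self.class_order:
            sel = (self.data[self.group_col] == cls).to_numpy()
            g = transformed[sel]
            groups.append(g)
            res.group_medians[cls] = float(np.median(pooled[sel]))
            if 3 <= len(g) <= 5000:
                res.sw_p[cls] = normality_screen(g)
        ok, worst = variance_ratio_screen(groups, cfg.variance_ratio_bounds)
        if not ok:
            res.excluded = True
            res.exclusion_reason = f"variance ratio {worst:.3g} outside bounds"
            return res
        try:
            _, res.bf_p = brown_forsythe(groups)
        except ValueError:
            pass
        if len(groups) == 2:
            res.test = "MW"
            res.statistic, res.p, res.effect = mann_whitney_rb(*groups)
        else:
            res.test = "KW"
            res.statistic, res.p, res.effect = kruskal_eta2(groups)
            res.posthoc_p = bonferroni_posthoc(groups)
        res.effect_band = classify_effect(res.effect, res.test)
        return res

    def fit(self) -> "StudyResults":
        from .pipeline import classify_feature_name

        results: List[TestResult] = []
        for name in self.feature_columns:
            try:
                meta = classify_feature_name(name)
            except KeyError:
                meta = {"data_kind": "", "category": "", "camera": "none"}
            results.append(self._analyse_feature(name, meta))
        return StudyResults(self, results)


class StudyResults:
    """Fit output: per-feature test results with effect sizes.

    ``results`` holds the significant features (p < alpha) sorted by
    effect size descending, mirroring the study's result tables;
    ``all_results`` and ``excluded`` give the full picture.
    """

    def __init__(self, model: ArticulationStudy, results: List[TestResult]):
        self.model = model
        self._results = results

    # -- tabular views ------------------------------------------------------

    def _row(self, r: TestResult) -> dict:
        row = dict(
            feature=r.feature_name,
            data=r.data_kind,
            type=r.category,
            camera="" if r.camera == "none" else r.camera,
            test=r.test,
            p=r.p,
            statistic=r.statistic,
            effect=r.effect,
            effect_band=r.effect_band,
            log_transformed=r.log_transformed,
            bf_p=r.bf_p,
        )
        for pair, p in r.posthoc_p.items():
            row[f"posthoc_{pair}"] = p
        for cls, med in r.group_medians.items():
            row[f"median_{cls}"] = med
        return row

    @property
    def all_results(self) -> pd.DataFrame:
        rows = [self._row(r) for r in self._results if not r.excluded]
        return pd.DataFrame(rows)

    @property
    def excluded(self) -> pd.DataFrame:
        rows = [
            dict(feature=r.feature_name, reason=r.exclusion_reason)
            for r in self._results
            if r.excluded
        ]
        return pd.DataFrame(rows, columns=["feature", "reason"])

    @property
    def results(self) -> pd.DataFrame:
        df = self.all_results
        if df.empty:
            return df
        df = df[df["p"] < self.model.config.alpha]
        df = df.sort_values("effect", ascending=False, kind="mergesort")
        df.insert(0, "no", range(1, len(df) + 1))
        return df.reset_index(drop=True)

    def result_for(self, feature: str) -> TestResult:
        for r in self._results:
            if r.feature_name == feature:
                return r
        raise KeyError(feature)

    # -- reporting ----------------------------------------------------------

    def summary(self, max_rows: int = 20) -> str:
        sig = self.results
        k = len(self.model.class_order)
        lines = [
            f"Articulation study: {self.model.sibilant.ipa} "
            f"({', '.join(self.model.class_order)})",
            f"speakers: {len(self.model.data)}   features tested: "
            f"{len(self._results) - len(self.excluded)}   excluded: {len(self.excluded)}",
            f"test: {'Mann-Whitney U + rb' if k == 2 else 'Kruskal-Wallis + eta2'}"
            f"   alpha = {self.model.config.alpha}",
            f"significant features: {len(sig)}",
            "",
        ]
        if not sig.empty:
            cols = ["no", "feature", "data", "type", "camera", "p", "statistic", "effect", "effect_band"]
            shown = sig[cols].head(max_rows).copy()
            shown["p"] = shown["p"].map(lambda v: f"{v:.3g}")
            shown["statistic"] = shown["statistic"].map(lambda v: f"{v:.3f}")
            shown["effect"] = shown["effect"].map(lambda v: f"{v:.3f}")
            lines.append(shown.to_string(index=False))
            if len(sig) > max_rows:
                lines.append(f"... ({len(sig) - max_rows} more rows)")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        from .corpus_io import write_feature_table

        write_feature_table(self.results, path)

    # -- plotting -----------------------------------------------------------

    def plot_feature(self, feature: str, ax=None):
        """Box plot of one feature's per-class distributions."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        data = [
            self.model.data.loc[
                self.model.data[self.model.group_col] == cls, feature
            ].to_numpy(dtype=float)
            for cls in self.model.class_order
        ]
        ax.boxplot(data, tick_labels=self.model.class_order)
        ax.set_title(feature)
        ax.set_ylabel(feature)
        return ax

    def plot_top(self, k: int = 3, path=None):
        """Box plots of the k largest-effect significant features."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        sig = self.results
        names = sig["feature"].head(k).tolist()
        if not names:
            return None
        fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2))
        axes = np.atleast_1d(axes)
        for ax, name in zip(axes, names):
            self.plot_feature(name, ax=ax)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
        return fig


def run_study(
    speaker_table: pd.DataFrame,
    sibilant,
    config: Optional[PipelineConfig] = None,
    **kwargs,
) -> StudyResults:
    """Functional wrapper: fit an :class:`ArticulationStudy` in one call."""
    return ArticulationStudy(speaker_table, sibilant, config=config, **kwargs).fit()
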