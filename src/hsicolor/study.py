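"""Study-design accounting, product-effect ANOVA/Tukey ranking, and
repeatability/reproducibility correlation analysis.

A product-screening study applies each of several foundation products to a
panel of models, imaging before (T_0) and immediately after (T_imm)
application; the product *effect* is the change in ROI-mean L*, a*, b* (and
the ΔE of the mean colors). Effects are ranked per
instrument-operator-repetition subset: one-way ANOVA across products gates a
Tukey HSD multiple comparison, and the result is rendered as a compact
ranking string — products ordered by mean effect ascending (most negative
first), commas separating statistically distinct groups, e.g. ``"AC,B"``.

Group structure follows the compact-letter-display convention: each group is
a maximal set of products that are pairwise non-significantly different, and
``n_groups`` counts those sets. For clean separations this coincides with
splitting the ordered means at significant gaps; when the sets overlap (A~C
and C~B but A!=B) the shared product is displayed with the group whose
members it resembles most and the result is flagged ``overlapping``.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

EFFECT_CHANNELS = ("dL", "da", "db", "dE")


# ---------------------------------------------------------------------------
# study design accounting


@dataclass(frozen=True)
class StudyDesign:
    """Counts and labels defining a screening study.

    The validation study: 3 products on 9 models, imaged at 2 time points,
    repeated twice, duplicated by 2 operators on the imager, with a
    single-spot spectroradiometer measurement per repetition.
    """

    n_models: int = 9
    products: tuple[str, ...] = ("A", "B", "C")
    n_repetitions: int = 2
    operators: tuple[str, ...] = ("Op.1", "Op.2")
    instruments: tuple[str, ...] = ("HSI", "PR-650")
    time_points: tuple[str, ...] = ("T0", "Timm")

    def __post_init__(self) -> None:
        if min(self.n_models, len(self.products), self.n_repetitions,
               len(self.operators), len(self.instruments),
               len(self.time_points)) < 1:
            raise ValidationError("all design counts must be >= 1")
        if len(set(self.products)) != len(self.products):
            raise ValidationError("product labels must be unique")


@dataclass(frozen=True)
class DesignCounts:
    hsi_images: int
    spectra: int
    independent_tests: int


def enumerate_design(design: StudyDesign) -> DesignCounts:
    """Expected acquisition counts for a design.

    Imager cubes: models x products x time points x repetitions x operators.
    Spectroradiometer spectra: models x products x time points x repetitions
    (one operator). Independent tests: products x repetitions x instruments.
    """
    base = design.n_models * len(design.products) * len(design.time_points) \
        * design.n_repetitions
    return DesignCounts(
        hsi_images=base * len(design.operators),
        spectra=base,
        independent_tests=len(design.products) * design.n_repetitions
        * len(design.instruments),
    )


SessionKey = tuple  # (model, product, repetition, operator)


def account_missing(
    acquired: Sequence[tuple],
    design: StudyDesign,
) -> dict:
    """Pair T_0/T_imm acquisitions into time-difference data points.

    ``acquired`` lists (model, product, repetition, operator, time_point)
    keys of the images actually on disk. A session contributes a pair only
    when both of its time points exist, so removing either image of a
    session removes exactly one pair.
    """
    if len(set(acquired)) != len(acquired):
        raise ValidationError("duplicate acquisition keys")
    t0, t1 = design.time_points
    sessions: dict[SessionKey, set] = {}
    for key in acquired:
        *session, tp = key
        if tp not in design.time_points:
            raise ValidationError(f"unknown time point {tp!r}")
        sessions.setdefault(tuple(session), set()).add(tp)
    pairs = [s for s, tps in sessions.items() if {t0, t1} <= tps]
    incomplete = [s for s, tps in sessions.items() if {t0, t1} - tps]
    return {
        "n_images": len(acquired),
        "n_pairs": len(pairs),
        "pairs": sorted(pairs),
        "incomplete_sessions": sorted(incomplete),
    }


# ---------------------------------------------------------------------------
# ANOVA and Tukey grouping


@dataclass(frozen=True)
class SummaryStats:
    """Per-group mean, sample SD, and size (sufficient for one-way ANOVA)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("each group needs n >= 2")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float


def _summaries_from_raw(groups: Mapping[str, Sequence[float]]) -> dict[str, SummaryStats]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"group {name!r} has n < 2")
        out[name] = SummaryStats(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA on raw per-group samples (via scipy)."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs n >= 2")
    summ = _summaries_from_raw(groups)
    n_tot = sum(s.n for s in summ.values())
    dfw = n_tot - len(groups)
    ssw = sum((s.n - 1) * s.sd**2 for s in summ.values())
    allvals = np.concatenate(arrays)
    if np.ptp(allvals) == 0:
        # degenerate: every observation identical -> no evidence of effect
        return AnovaResult(0.0, 1.0, len(groups) - 1, dfw, 0.0)
    F, p = sps.f_oneway(*arrays)
    return AnovaResult(float(F), float(p), len(groups) - 1, dfw, ssw / dfw)


def anova_from_summary(summaries: Mapping[str, SummaryStats]) -> AnovaResult:
    """One-way ANOVA from group means/SDs/sizes only.

    SSB = sum n_i (mean_i - grand)^2 and SSW = sum (n_i - 1) sd_i^2 recover
    the raw-data F exactly when the summaries derive from the raw samples.
    """
    if len(summaries) < 2:
        raise ValidationError("need at least 2 groups")
    ns = np.array([s.n for s in summaries.values()], dtype=float)
    means = np.array([s.mean for s in summaries.values()])
    sds = np.array([s.sd for s in summaries.values()])
    grand = float((ns * means).sum() / ns.sum())
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb = len(summaries) - 1
    dfw = int(ns.sum()) - len(summaries)
    msb, msw = ssb / dfb, ssw / dfw
    if msw == 0.0:
        F = np.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        F = msb / msw
        p = float(sps.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), p, dfb, dfw, msw)


@dataclass
class GroupingResult:
    """ANOVA F/p plus the Tukey subgroup structure and its ranking string."""

    F: float
    p: float
    groups: list[tuple[str, ...]]      # letter-display sets, ascending by mean
    ranking_string: str
    n_groups: int
    means: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    alpha: float
    overlapping: bool = False
    anova_gated: bool = False          # True when ANOVA failed to reject


def _maximal_nonsig_sets(
    products: Sequence[str], nonsig: set[frozenset]
) -> list[set]:
    """Maximal sets of mutually non-significant products (letter display).

    Product counts here are tiny (a handful of formulas), so plain subset
    enumeration is clearer than a clique algorithm.
    """
    items = list(products)
    cliques: list[set] = []
    for r in range(len(items), 0, -1):
        for combo in itertools.combinations(items, r):
            s = set(combo)
            if any(s <= c for c in cliques):
                continue
            if all(frozenset(p) in nonsig for p in itertools.combinations(combo, 2)):
                cliques.append(s)
    return cliques


@lru_cache(maxsize=256)
def _q_critical(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_grouping(
    data: Mapping[str, Sequence[float]] | Mapping[str, SummaryStats],
    alpha: float = 0.01,
    gate_on_anova: bool = True,
    compute_p: bool = True,
) -> GroupingResult:
    """One-way ANOVA followed by Tukey HSD grouping into distinct subsets.

    Accepts raw per-group samples or :class:`SummaryStats` per group.
    Pairwise significance uses the studentized-range distribution with the
    Tukey-Kramer standard error for unequal group sizes; the decision
    compares the observed range statistic against the cached critical value
    ``q(alpha, k, df)``, and exact pairwise p-values are attached when
    ``compute_p`` (skipping them speeds up large simulations). When
    ``gate_on_anova`` (the default, matching the protocol of grouping "if
    warranted") and the ANOVA p-value is not below ``alpha``, all products
    form a single group.
    """
    first = next(iter(data.values()))
    if isinstance(first, SummaryStats):
        summaries = dict(data)  # type: ignore[arg-type]
        anova = anova_from_summary(summaries)
    else:
        summaries = _summaries_from_raw(data)  # type: ignore[arg-type]
        anova = anova_oneway(data)  # type: ignore[arg-type]

    names = sorted(summaries, key=lambda k: summaries[k].mean)
    means = {k: summaries[k].mean for k in names}
    k_groups, dfw, msw = len(names), anova.df_within, anova.ms_within

    gated = gate_on_anova and not (anova.p < alpha)
    pairwise_p: dict[tuple[str, str], float] = {}
    nonsig: set[frozenset] = set()
    if not gated:
        q_crit = _q_critical(alpha, k_groups, dfw)
        for g1, g2 in itertools.combinations(names, 2):
            s1, s2 = summaries[g1], summaries[g2]
            se = np.sqrt(msw / 2.0 * (1.0 / s1.n + 1.0 / s2.n))
            if se == 0.0:
                significant = s1.mean != s2.mean
                q_obs = np.inf if significant else 0.0
            else:
                q_obs = abs(s1.mean - s2.mean) / se
                significant = q_obs > q_crit
            if compute_p:
                if np.isinf(q_obs):
                    pairwise_p[(g1, g2)] = 0.0
                else:
                    pairwise_p[(g1, g2)] = float(
                        sps.studentized_range.sf(q_obs, k_groups, dfw)
                    )
            if not significant:
                nonsig.add(frozenset((g1, g2)))

    if gated:
        cliques = [set(names)]
    else:
        cliques = _maximal_nonsig_sets(names, nonsig)

    cliques.sort(key=lambda s: min(means[p] for p in s))
    overlapping = sum(len(c) for c in cliques) > len(names)
    # render as a partition: each product joins the clique whose member mean
    # is closest to its own (display choice only; `groups` keeps the cliques)
    assigned: dict[str, int] = {}
    for name in names:
        candidates = [i for i, c in enumerate(cliques) if name in c]
        if len(candidates) == 1:
            assigned[name] = candidates[0]
        else:
            def dist(i: int) -> float:
                others = [means[p] for p in cliques[i]]
                return abs(float(np.mean(others)) - means[name])
            assigned[name] = min(candidates, key=dist)
    blocks = [
        [n for n in names if assigned[n] == i]
        for i in range(len(cliques))
    ]
    ranking = ",".join("".join(b) for b in blocks if b)

    return GroupingResult(
        F=anova.F, p=anova.p,
        groups=[tuple(sorted(c, key=lambda p: means[p])) for c in cliques],
        ranking_string=ranking,
        n_groups=len(cliques),
        means=means,
        pairwise_p=pairwise_p,
        alpha=alpha,
        overlapping=overlapping,
        anova_gated=gated,
    )


def parse_ranking(ranking_string: str) -> list[tuple[str, ...]]:
    """Parse a ranking string like ``"AC,B"`` back into its group partition."""
    if not ranking_string:
        raise ValidationError("empty ranking string")
    return [tuple(block) for block in ranking_string.split(",")]


# ---------------------------------------------------------------------------
# correlation / repeatability metrics


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    pearson_r: float
    spearman_rho: float
    percent_nl: float
    delta_plus: float
    delta_minus: float
    mean_abs_diff: float        # mean |y - x| over pairs
    mae: float                  # mean |group-mean difference| (Figure-4 style)
    maximum_signal: float
    n: int


def percent_nonlinearity(
    x: np.ndarray,
    y: np.ndarray,
    slope: float,
    intercept: float,
    maximum_signal: float | None = None,
) -> tuple[float, float, float]:
    """Percent nonlinearity of paired data about a linear fit.

    ``%NL = 100 * (delta_plus + |delta_minus|) / MaximumSignal`` where
    delta_plus / delta_minus are the extreme positive and negative residuals
    ``y - (slope * x + intercept)``. MaximumSignal defaults to ``max |y|``
    over the pairs, which keeps the statistic scale-invariant.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    resid = y - (slope * x + intercept)
    d_plus = float(max(resid.max(), 0.0))
    d_minus = float(min(resid.min(), 0.0))
    if maximum_signal is None:
        maximum_signal = float(np.abs(y).max())
    if maximum_signal <= 0:
        raise ValidationError("MaximumSignal must be positive")
    return 100.0 * (d_plus + abs(d_minus)) / maximum_signal, d_plus, d_minus


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    group_labels: Sequence | None = None,
    maximum_signal: float | None = None,
) -> CorrelationResult:
    """Least-squares fit plus rank/linear correlation of matched measurements.

    ``y`` is regressed on ``x`` (ordinary least squares); Pearson r and
    Spearman rho (average-rank ties) quantify linearity and monotonicity.
    ``mean_abs_diff`` is the mean absolute pairwise difference; ``mae`` is
    the mean absolute difference between per-group means when
    ``group_labels`` is given (else it equals ``mean_abs_diff``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in x or y")
    fit = sps.linregress(x, y)
    rho = float(sps.spearmanr(x, y).statistic)
    pnl, d_plus, d_minus = percent_nonlinearity(
        x, y, fit.slope, fit.intercept, maximum_signal
    )
    mad = float(np.abs(y - x).mean())
    if group_labels is not None:
        df = pd.DataFrame({"g": list(group_labels), "x": x, "y": y})
        gm = df.groupby("g").mean()
        mae = float(np.abs(gm["y"] - gm["x"]).mean())
    else:
        mae = mad
    return CorrelationResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue), spearman_rho=rho,
        percent_nl=pnl, delta_plus=d_plus, delta_minus=d_minus,
        mean_abs_diff=mad, mae=mae,
        maximum_signal=maximum_signal if maximum_signal is not None
        else float(np.abs(y).max()),
        n=int(x.size),
    )


@dataclass(frozen=True)
class BoxplotSummary:
    Q1: float
    Q2: float
    Q3: float
    mean: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(samples: Sequence[float]) -> BoxplotSummary:
    """Quartiles (linear interpolation), 1.5-IQR whiskers, and outliers."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 1:
        raise ValidationError("need at least one sample")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    wlo = float(inside.min()) if inside.size else float(q1)
    whi = float(inside.max()) if inside.size else float(q3)
    outliers = tuple(float(v) for v in np.sort(arr[(arr < lo_fence) | (arr > hi_fence)]))
    return BoxplotSummary(float(q1), float(q2), float(q3), float(arr.mean()),
                          wlo, whi, outliers)


# ---------------------------------------------------------------------------
# end-to-end replication analysis


REQUIRED_EFFECT_COLUMNS = (
    "model", "product", "repetition", "operator", "instrument",
    "dL", "da", "db", "dE",
)


@dataclass
class ReplicationReport:
    """Full study analysis: per-subset groupings plus cross-subset correlations."""

    groupings: pd.DataFrame
    operator_correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    repetition_correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def summary_text(self) -> str:
        lines = ["Per-subset product grouping (ranking ascending, commas = distinct groups):"]
        for _, row in self.groupings.iterrows():
            lines.append(
                f"  {row.instrument} rep{row.repetition} {row.operator} "
                f"{row.parameter}: {row.ranking} (groups={row.n_groups}, "
                f"F={row.F:.2f}, p={row.p:.2e})"
            )
        for title, corr in (("operator", self.operator_correlations),
                            ("repetition", self.repetition_correlations)):
            if corr:
                lines.append(f"Between-{title} correlations:")
                for ch, c in corr.items():
                    lines.append(
                        f"  {ch}: slope={c.slope:.3f} intercept={c.intercept:.3f} "
                        f"r={c.pearson_r:.3f} rho={c.spearman_rho:.3f} "
                        f"%NL={c.percent_nl:.1f} mean|diff|={c.mean_abs_diff:.3f}"
                    )
        lines.extend(f"WARNING: {w}" for w in self.warnings)
        return "\n".join(lines)


def run_replication(
    effects: pd.DataFrame,
    alpha: float = 0.01,
    maximum_signal: float | None = None,
) -> ReplicationReport:
    """Grouping analysis per instrument-repetition-operator subset plus
    operator-vs-operator and repetition-vs-repetition correlations.

    ``effects`` is the tidy per-session effect table (one row per
    model-product-repetition-operator-instrument, columns dL/da/db/dE).
    Subsets with a missing product or singleton groups are skipped with a
    warning rather than failing the whole analysis.
    """
    missing = [c for c in REQUIRED_EFFECT_COLUMNS if c not in effects.columns]
    if missing:
        raise ValidationError(f"effects table missing columns {missing}")
    effects = effects.drop_duplicates(
        subset=["model", "product", "repetition", "operator", "instrument"]
    )
    warnings: list[str] = []
    rows = []
    for (instr, rep, op), sub in effects.groupby(
        ["instrument", "repetition", "operator"], sort=True
    ):
        for channel in EFFECT_CHANNELS:
            groups = {
                prod: g[channel].to_numpy()
                for prod, g in sub.groupby("product")
            }
            if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
                warnings.append(
                    f"subset {instr}/rep{rep}/{op}/{channel} skipped "
                    f"(insufficient groups)"
                )
                continue
            res = tukey_grouping(groups, alpha=alpha)
            rows.append({
                "instrument": instr, "repetition": rep, "operator": op,
                "parameter": channel, "ranking": res.ranking_string,
                "n_groups": res.n_groups, "F": res.F, "p": res.p,
                "overlapping": res.overlapping,
            })
    groupings = pd.DataFrame(rows)

    def _paired(frame: pd.DataFrame, split_col: str, keys: list[str]) -> dict:
        levels = sorted(frame[split_col].unique())
        out: dict[str, CorrelationResult] = {}
        if len(levels) != 2:
            return out
        a = frame[frame[split_col] == levels[0]].set_index(keys)
        b = frame[frame[split_col] == levels[1]].set_index(keys)
        common = a.index.intersection(b.index)
        if len(common) < 3:
            warnings.append(f"too few pairs to correlate across {split_col}")
            return out
        for channel in ("dL", "da", "db"):
            try:
                out[channel] = correlate(
                    a.loc[common, channel], b.loc[common, channel],
                    group_labels=[i[1] for i in common],  # product label
                    maximum_signal=maximum_signal,
                )
            except ValidationError as exc:
                warnings.append(f"{split_col}/{channel}: {exc}")
        return out

    hsi = effects[effects["instrument"] == "HSI"]
    op_corr = _paired(hsi, "operator", ["model", "product", "repetition"])
    rep_corr = _paired(hsi, "repetition", ["model", "product", "operator"])
    return ReplicationReport(groupings, op_corr, rep_corr, warnings)
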