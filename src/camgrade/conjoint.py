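"""Conjoint analysis: ANOVA and Duncan's multiple range test across stages.

Once fruit have been graded, the question is whether the image-derived
stages differ in the things an agronomist actually cares about — seed oil
content, moisture, weights, and so on.  For each property this module
runs a one-way ANOVA across the stages followed by Duncan's multiple
range test (p ≤ 0.05 by default), and renders the familiar
"mean ± SD letter" table in which groups sharing a letter were not
separated.

Duncan's test compares the descending-sorted group means with
span-dependent least significant ranges

    R_p = q(1 − αp, p, df) · sqrt(MSE / n_h),   αp = 1 − (1 − α)^(p−1)

where ``q`` is the studentized range quantile, ``p`` the number of means
spanned, MSE/df come from the ANOVA, and ``n_h`` is the (harmonic mean)
group size.  A span whose extreme means differ by less than its range is
declared homogeneous, and homogeneity of a span protects every span it
contains (the classical step-down rule).  Compact letters are the
maximal homogeneous stretches of the sorted means.

Assays reported as means of few replicate determinations can be analysed
with the replicate design rather than the per-fruit sample count via the
``n_effective``/``df_effective`` parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from camgrade.synthetic import STAGES, SamplePropertyRecord

#: Properties analysed by default, with display units.
PROPERTY_UNITS = {
    "transverse_diameter_mm": "mm",
    "vertical_diameter_mm": "mm",
    "dry_seed_weight_g": "g",
    "moisture_pct": "%",
    "oil_pct": "%",
    "soluble_protein_pct": "%",
    "soluble_sugar_pct": "%",
    "starch_pct": "%",
}


@dataclass
class PropertyGroups:
    """Per-stage value vectors of one measured property."""

    name: str
    groups: dict[str, np.ndarray]
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 stages")
        clean = {}
        for stage, values in self.groups.items():
            v = np.asarray(values, dtype=np.float64)
            if v.ndim != 1 or len(v) < 2:
                raise ValueError(f"stage {stage!r} needs >= 2 values")
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite values in stage {stage!r}")
            clean[stage] = v
        self.groups = clean


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    mse: float
    df_error: int
    df_between: int
    group_means: dict[str, float]
    group_sizes: dict[str, int]


def one_way_anova(groups: PropertyGroups) -> AnovaResult:
    """Classical between/within sum-of-squares decomposition."""
    values = list(groups.groups.values())
    all_values = np.concatenate(values)
    grand = all_values.mean()
    k = len(values)
    n = len(all_values)
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in values)
    df_between = k - 1
    df_error = n - k
    ms_between = ss_between / df_between
    mse = ss_within / df_error
    if mse == 0:
        if ms_between == 0:
            raise ValueError(
                "degenerate input: zero within-group variance with equal means")
        return AnovaResult(np.inf, 0.0, 0.0, df_error, df_between,
                           {s: float(v.mean()) for s, v in groups.groups.items()},
                           {s: len(v) for s, v in groups.groups.items()})
    f = ms_between / mse
    p = float(stats.f.sf(f, df_between, df_error))
    return AnovaResult(float(f), p, float(mse), df_error, df_between,
                       {s: float(v.mean()) for s, v in groups.groups.items()},
                       {s: len(v) for s, v in groups.groups.items()})


def _least_significant_ranges(k: int, mse: float, df: int, n_h: float,
                              alpha: float) -> dict[int, float]:
    """R_p for spans p = 2..k under Duncan's protection levels."""
    ranges = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))
        ranges[p] = q * np.sqrt(mse / n_h)
    return ranges


def _compact_letters(nonsig: np.ndarray) -> list[str]:
    """Letters from a homogeneity matrix over descending-sorted means.

    Maximal homogeneous stretches [i..j] each get one letter; stretches
    contained in a larger one are absorbed.
    """
    k = nonsig.shape[0]
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # absorb intervals contained in an earlier, wider one
    kept = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in intervals):
            if iv not in kept:
                kept.append(iv)
    letters = [""] * k
    for letter_idx, (i, j) in enumerate(sorted(kept)):
        ch = chr(ord("a") + letter_idx)
        for pos in range(i, j + 1):
            letters[pos] += ch
    return letters


@dataclass
class DuncanResult:
    """Duncan's multiple range test outcome for one property."""

    name: str
    units: str
    anova: AnovaResult
    alpha: float
    stage_order: list[str]             # by descending mean
    sorted_means: np.ndarray
    ranges: dict[int, float]           # span -> least significant range
    letters: dict[str, str]            # stage -> compact letters
    pairwise_significant: dict[tuple[str, str], bool]
    n_h: float
    group_sds: dict[str, float] = field(default_factory=dict)

    def separated(self, stage_a: str, stage_b: str) -> bool:
        key = tuple(sorted((stage_a, stage_b)))
        return self.pairwise_significant[key]

    @property
    def fully_separated(self) -> bool:
        """True when no two stages share any letter."""
        return all(self.pairwise_significant.values())

    @property
    def n_distinct_letters(self) -> int:
        return len(set("".join(self.letters.values())))


def duncan_mrt(groups: PropertyGroups, alpha: float = 0.05,
               n_effective: float | None = None,
               df_effective: int | None = None) -> DuncanResult:
    """Duncan's multiple range test with compact letter display.

    ``n_effective``/``df_effective`` override the group size and error df
    used for the ranges (e.g. a triplicate-determination design analysed
    from per-fruit draws); the MSE always comes from the data.
    """
    if len(groups.groups) < 2:
        raise ValueError("need at least two groups")
    anova = one_way_anova(groups)
    if anova.df_error < 1:
        raise ValueError("ANOVA error degrees of freedom must be >= 1")
    sizes = np.array(list(anova.group_sizes.values()), dtype=np.float64)
    if n_effective is not None:
        if n_effective <= 1:
            raise ValueError("n_effective must exceed 1")
        n_h = float(n_effective)
        df = df_effective if df_effective is not None else int(
            round(len(sizes) * (n_effective - 1)))
    else:
        n_h = float(len(sizes) / np.sum(1.0 / sizes))
        df = anova.df_error
    stages = list(groups.groups)
    means = np.array([anova.group_means[s] for s in stages])
    order = np.argsort(-means)
    stage_order = [stages[i] for i in order]
    sorted_means = means[order]
    k = len(stages)
    ranges = _least_significant_ranges(k, anova.mse, df, n_h, alpha)

    # Step-down: homogeneity of a span protects all contained spans.
    nonsig = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(nonsig, True)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if nonsig[i, j]:
                continue
            diff = sorted_means[i] - sorted_means[j]
            if diff <= ranges[span] or _is_protected(nonsig, i, j):
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        nonsig[a, b] = nonsig[b, a] = True

    letters_sorted = _compact_letters(nonsig)
    letters = {stage_order[i]: letters_sorted[i] for i in range(k)}
    pairwise = {}
    for a in range(k):
        for b in range(a + 1, k):
            key = tuple(sorted((stage_order[a], stage_order[b])))
            pairwise[key] = not nonsig[a, b]
    sds = {s: float(np.std(groups.groups[s], ddof=1)) for s in stages}
    return DuncanResult(name=groups.name, units=groups.units, anova=anova,
                        alpha=alpha, stage_order=stage_order,
                        sorted_means=sorted_means, ranges=ranges,
                        letters=letters, pairwise_significant=pairwise,
                        n_h=n_h, group_sds=sds)


def _is_protected(nonsig: np.ndarray, i: int, j: int) -> bool:
    """A span already inside a declared-homogeneous wider span."""
    k = nonsig.shape[0]
    for a in range(0, i + 1):
        for b in range(j, k):
            if (a, b) != (i, j) and nonsig[a, b] and b - a > j - i:
                return True
    return False


@dataclass
class ConjointResults:
    """Per-property Duncan results with a publication-style table."""

    results: dict[str, DuncanResult]
    flagged: dict[str, str]
    alpha: float
    stage_names: tuple[str, ...] = STAGES

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for prop, res in self.results.items():
            row: dict[str, object] = {"property": prop, "units": res.units,
                                      "F": res.anova.f_statistic,
                                      "p": res.anova.p_value}
            for stage in self.stage_names:
                if stage in res.letters:
                    row[f"{stage}_mean"] = res.anova.group_means[stage]
                    row[f"{stage}_sd"] = res.group_sds[stage]
                    row[f"{stage}_letter"] = res.letters[stage]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        width = max(len(p) for p in list(self.results) + list(self.flagged))
        header = f"{'Property':<{width}}  " + "  ".join(
            f"{s:>16}" for s in self.stage_names)
        lines = [header, "-" * len(header)]
        for prop, res in self.results.items():
            cells = []
            for stage in self.stage_names:
                m = res.anova.group_means[stage]
                sd = res.group_sds[stage]
                cells.append(f"{m:7.2f} ± {sd:4.2f} {res.letters[stage]:<2}")
            lines.append(f"{prop:<{width}}  " + "  ".join(cells))
        for prop, reason in self.flagged.items():
            lines.append(f"{prop:<{width}}  [not computed: {reason}]")
        lines.append(f"Different letters in a row differ at p <= {self.alpha} "
                     "(Duncan's multiple range test).")
        return "\n".join(lines)


def conjoint_report(records: Sequence[SamplePropertyRecord],
                    stage_labels: Sequence[str] | None = None,
                    alpha: float = 0.05,
                    n_effective: float | None = None,
                    df_effective: int | None = None,
                    properties: Sequence[str] | None = None) -> ConjointResults:
    """Run ANOVA + Duncan for every property across the labelled stages.

    ``stage_labels`` (e.g. cluster-derived stages) override the records'
    own truth stages when given.  A property whose groups cannot be formed
    (a stage with fewer than two records, or a degenerate ANOVA) is
    flagged rather than computed.  Record order does not matter.
    """
    records = list(records)
    if stage_labels is None:
        labels = [r.stage for r in records]
    else:
        labels = list(stage_labels)
        if len(labels) != len(records):
            raise ValueError("stage_labels must align with records")
    props = list(properties) if properties is not None else list(PROPERTY_UNITS)
    results: dict[str, DuncanResult] = {}
    flagged: dict[str, str] = {}
    present = [s for s in STAGES if s in set(labels)]
    for prop in props:
        groups = {}
        for stage in present:
            vals = np.array([getattr(r, prop) for r, l in zip(records, labels)
                             if l == stage])
            groups[stage] = vals
        small = [s for s, v in groups.items() if len(v) < 2]
        if len(groups) < 2 or small:
            flagged[prop] = (f"stage(s) {small} have < 2 records" if small
                             else "fewer than 2 stages")
            continue
        try:
            pg = PropertyGroups(name=prop, groups=groups,
                                units=PROPERTY_UNITS.get(prop, ""))
            results[prop] = duncan_mrt(pg, alpha=alpha, n_effective=n_effective,
                                       df_effective=df_effective)
        except ValueError as exc:
            flagged[prop] = str(exc)
    return ConjointResults(results=results, flagged=flagged, alpha=alpha,
                           stage_names=tuple(present))
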