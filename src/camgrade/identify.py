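"""Stage naming, confusion matrices, and identification metrics.

Clusters coming out of the grading loop are anonymous; this module names
them as maturity stages (from anchor labels or a maturity proxy), builds
true-by-predicted confusion matrices, and computes the standard
one-vs-rest identification metrics: per-stage precision, recall, F1, and
overall accuracy.  It also houses the moisture-content formula that links
the fresh and dry seed weights in the property tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.optimize import linear_sum_assignment

from camgrade.synthetic import STAGES


def moisture_content(w_fresh: float, w_dry: float) -> float:
    """Seed moisture content in percent: 100·(W_f − W_d)/W_f.

    Requires W_f ≥ W_d > 0.
    """
    if w_dry <= 0 or w_fresh <= 0:
        raise ValueError("weights must be positive")
    if w_dry > w_fresh:
        raise ValueError("dry weight cannot exceed fresh weight")
    return 100.0 * (w_fresh - w_dry) / w_fresh


@dataclass
class ConfusionMatrix:
    """k×k counts; rows are true stages, columns predicted stages."""

    counts: np.ndarray
    stage_names: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.stage_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}×{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def one_vs_rest(self, stage_index: int) -> dict[str, int]:
        """TP/FP/FN/TN of one stage against the rest."""
        c = self.counts
        tp = int(c[stage_index, stage_index])
        fp = int(c[:, stage_index].sum() - tp)
        fn = int(c[stage_index, :].sum() - tp)
        tn = self.n - tp - fp - fn
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def round2(x: float) -> float:
    """Round half-up to two decimals (table display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class StageMetrics:
    """Per-stage precision/recall/F1 (percent) and overall accuracy.

    Values are stored at full precision; ``rounded()`` and ``summary()``
    apply the two-decimal half-up display convention.  A stage whose
    precision denominator is zero (never predicted) carries ``nan`` and
    is listed in ``undefined``.
    """

    stage_names: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    overall_accuracy: float
    undefined: tuple[str, ...] = ()

    def rounded(self) -> dict:
        out = {s: {"precision": round2(self.precision[i]),
                   "recall": round2(self.recall[i]),
                   "f1": round2(self.f1[i])}
               for i, s in enumerate(self.stage_names)
               if np.isfinite(self.precision[i])}
        for i, s in enumerate(self.stage_names):
            if not np.isfinite(self.precision[i]):
                out[s] = {"precision": None, "recall": round2(self.recall[i]),
                          "f1": None}
        out["overall_accuracy"] = round2(self.overall_accuracy)
        return out

    def summary(self) -> str:
        lines = ["Maturity      Prec (%)   Rec (%)    F1 (%)     OAcc (%)"]
        for i, s in enumerate(self.stage_names):
            prec = ("   -  " if not np.isfinite(self.precision[i])
                    else f"{round2(self.precision[i]):6.2f}")
            f1 = ("   -  " if not np.isfinite(self.f1[i])
                  else f"{round2(self.f1[i]):6.2f}")
            oacc = f"{round2(self.overall_accuracy):6.2f}" if i == 0 else ""
            lines.append(f"{s:<12}  {prec}     {round2(self.recall[i]):6.2f}"
                         f"     {f1}     {oacc}")
        return "\n".join(lines)


def build_confusion(true_stages, predicted_stages,
                    stage_names: tuple[str, ...] = STAGES) -> ConfusionMatrix:
    """Count true-by-predicted stage pairs."""
    t = list(true_stages)
    p = list(predicted_stages)
    if len(t) != len(p):
        raise ValueError("true and predicted labels must have equal length")
    index = {s: i for i, s in enumerate(stage_names)}
    k = len(stage_names)
    counts = np.zeros((k, k), dtype=np.int64)
    for ti, pi in zip(t, p):
        if ti not in index or pi not in index:
            raise ValueError(f"unknown label in pair ({ti!r}, {pi!r})")
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts=counts, stage_names=tuple(stage_names))


def compute_metrics(cm: ConfusionMatrix) -> StageMetrics:
    """One-vs-rest precision/recall/F1 per stage plus overall accuracy.

    Overall accuracy is the diagonal sum over the total count, which is
    what the one-vs-rest (TP+TN)/(TP+FP+FN+TN) formula micro-averages to
    in the multiclass setting.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    if (cm.counts.sum(axis=1) == 0).any():
        raise ValueError("every true stage needs at least one sample")
    k = len(cm.stage_names)
    prec = np.empty(k)
    rec = np.empty(k)
    f1 = np.empty(k)
    undefined = []
    for i in range(k):
        ovr = cm.one_vs_rest(i)
        denom_p = ovr["TP"] + ovr["FP"]
        prec[i] = 100.0 * ovr["TP"] / denom_p if denom_p else np.nan
        rec[i] = 100.0 * ovr["TP"] / (ovr["TP"] + ovr["FN"])
        if denom_p == 0 or prec[i] + rec[i] == 0:
            f1[i] = np.nan
            if denom_p == 0:
                undefined.append(cm.stage_names[i])
        else:
            f1[i] = 2.0 * prec[i] * rec[i] / (prec[i] + rec[i])
    return StageMetrics(stage_names=cm.stage_names, precision=prec, recall=rec,
                        f1=f1, overall_accuracy=100.0 * cm.n_correct / cm.n,
                        undefined=tuple(undefined))


@dataclass
class StageNaming:
    """Cluster-id → stage-name mapping plus how it was derived."""

    mapping: dict[int, str]
    mode: str                         # "anchors" or "proxy"
    flagged: bool = False             # True when a non-monotone proxy rule fired
    note: str = ""

    def apply(self, assignments) -> list[str]:
        return [self.mapping[int(a)] for a in assignments]


def map_clusters_to_stages(assignments, *, anchor_stages=None,
                           proxy_values=None, proxy_kind: str = "crack",
                           stage_names: tuple[str, ...] = STAGES) -> StageNaming:
    """Name anonymous clusters as maturity stages.

    Two evidence modes:

    * ``anchor_stages`` — true stages known for a subset of images (pass
      None for unknown entries); the naming is the Hungarian assignment
      maximising anchor agreement.
    * ``proxy_values`` — a per-image scalar maturity proxy.  With
      ``proxy_kind="crack"`` (crack/seed-exposure area, monotone in
      maturity) clusters are ranked by mean proxy: lowest → unripe,
      highest → overripe.  With ``proxy_kind="oil"`` the published
      low → high → mid trajectory of seed oil content is applied
      (lowest → unripe, highest → ripe, middle → overripe) and the
      naming is flagged as relying on that non-monotone ordering.
    """
    a = np.asarray(assignments)
    clusters = np.unique(a)
    k = len(stage_names)
    if anchor_stages is not None:
        anchors = list(anchor_stages)
        if len(anchors) != len(a):
            raise ValueError("anchor_stages must align with assignments")
        stage_index = {s: i for i, s in enumerate(stage_names)}
        contingency = np.zeros((len(clusters), k))
        cluster_pos = {int(c): i for i, c in enumerate(clusters)}
        n_anchors = 0
        for ci, st in zip(a, anchors):
            if st is None:
                continue
            contingency[cluster_pos[int(ci)], stage_index[st]] += 1
            n_anchors += 1
        if n_anchors == 0:
            raise ValueError("no anchor labels provided")
        rows, cols = linear_sum_assignment(-contingency)
        mapping = {int(clusters[r]): stage_names[c] for r, c in zip(rows, cols)}
        return StageNaming(mapping=mapping, mode="anchors",
                           note=f"{n_anchors} anchors")
    if proxy_values is not None:
        if k != 3:
            raise ValueError("proxy-based naming supports exactly 3 stages")
        v = np.asarray(proxy_values, dtype=np.float64)
        if len(v) != len(a):
            raise ValueError("proxy_values must align with assignments")
        if len(clusters) != 3:
            raise ValueError("proxy-based naming needs exactly 3 occupied clusters")
        means = np.array([v[a == c].mean() for c in clusters])
        order = np.argsort(means)      # ascending proxy
        if proxy_kind == "crack":
            ranked = ("unripe", "ripe", "overripe")
            flagged = False
            note = "clusters ranked by mean crack proxy (ascending)"
        elif proxy_kind == "oil":
            ranked = ("unripe", "overripe", "ripe")   # low → mid → high oil
            flagged = True
            note = ("oil proxy: lowest→unripe, highest→ripe, middle→overripe "
                    "(non-monotone trajectory)")
        else:
            raise ValueError(f"unknown proxy_kind {proxy_kind!r}")
        mapping = {int(clusters[order[i]]): ranked[i] for i in range(3)}
        return StageNaming(mapping=mapping, mode="proxy", flagged=flagged,
                           note=note)
    raise ValueError("provide anchor_stages or proxy_values as evidence")
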