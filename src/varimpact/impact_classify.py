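"""Control-calibrated benign/VUS/damaging classification.

Thresholds are set purely by the benign controls: for each metric, any value
whose "badness" is at or below the highest benign-control badness is benign,
anything up to twice that is a VUS, anything beyond is damaging.  A layer
(structure, pKa shift, dynamics, interactions, ...) takes the worst label of
its metrics, and a variant that is damaging in any layer is damaging
overall; one that is benign everywhere is benign; everything else is a VUS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricSpec",
    "ScoreTable",
    "ImpactLedger",
    "calibrate",
    "label_metric",
    "label_layer",
    "overall",
    "build_ledger",
]

SEVERITY = {"benign": 0, "VUS": 1, "damaging": 2}
LAYERS = ("sequence", "structure", "pka", "dynamics", "substrate_zn", "active_site")
ROLES = ("benign_control", "damaging_control", "query")


@dataclass(frozen=True)
class MetricSpec:
    """Registry entry for one metric: which layer it scores, how its value
    maps to badness, and its units.

    ``higher_is_worse``: badness = value clipped at zero (a stabilizing,
    negative delta counts as no badness); ``magnitude_is_worse``: badness =
    |value|.
    """

    layer: str
    orientation: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in {"higher_is_worse", "magnitude_is_worse"}:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def badness(self, value: float) -> float:
        if self.orientation == "magnitude_is_worse":
            return abs(value)
        return max(value, 0.0)


@dataclass
class ScoreTable:
    """Variant x metric values plus the metric and control registries.

    External columns (e.g. a folding ΔΔG from an outside tool) sit alongside
    internally computed metrics; they just need a registry entry.
    """

    values: pd.DataFrame  # index: variant, columns: metric
    metrics: dict[str, MetricSpec]
    roles: dict[str, str]  # variant -> benign_control | damaging_control | query

    def __post_init__(self) -> None:
        for metric in self.values.columns:
            if metric not in self.metrics:
                raise ValueError(f"metric {metric!r} missing from the registry")
        for variant in self.values.index:
            role = self.roles.get(variant)
            if role not in ROLES:
                raise ValueError(f"variant {variant!r} has no valid role (got {role!r})")
        if "benign_control" not in self.roles.values():
            raise ValueError("at least one benign control is required for calibration")

    @property
    def benign_controls(self) -> list[str]:
        return [v for v in self.values.index if self.roles[v] == "benign_control"]


@dataclass
class ImpactLedger:
    layer_labels: pd.DataFrame  # variant x layer
    overall_labels: pd.Series
    metric_labels: pd.DataFrame  # variant x metric
    calibration: dict[str, dict]
    roles: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.layer_labels.copy()
        out["overall"] = self.overall_labels
        out["role"] = [self.roles.get(v, "query") for v in out.index]
        return out

    def render(self) -> str:
        return self.to_frame().to_string()


def calibrate(
    score_table: ScoreTable,
    floor: float = 1e-6,
) -> dict[str, dict]:
    """Per-metric thresholds from the benign controls.

    b_max is the largest benign-control badness; the VUS bound is 2·b_max.
    A degenerate calibration (b_max below ``floor``) is replaced by the
    floor and recorded.
    """
    thresholds: dict[str, dict] = {}
    controls = score_table.benign_controls
    for metric in score_table.values.columns:
        spec = score_table.metrics[metric]
        vals = score_table.values.loc[controls, metric].dropna()
        if vals.empty:
            raise ValueError(f"metric {metric!r}: no benign-control values to calibrate")
        b_max = max(spec.badness(v) for v in vals)
        floored = b_max < floor
        if floored:
            b_max = floor
        thresholds[metric] = {
            "b_max": float(b_max),
            "vus_bound": float(2.0 * b_max),
            "floored": floored,
            "n_controls": int(vals.size),
        }
    return thresholds


def label_metric(value: float, thresholds: dict, spec: MetricSpec) -> str:
    """benign if badness ≤ b_max, VUS if ≤ 2·b_max, damaging beyond;
    a missing value is labelled ``missing``."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    badness = spec.badness(float(value))
    if badness <= thresholds["b_max"]:
        return "benign"
    if badness <= thresholds["vus_bound"]:
        return "VUS"
    return "damaging"


def label_layer(metric_labels: list[str], mode: str = "worst") -> str:
    """Collective label of one layer: maximum severity across its metrics
    (``worst``, the default) or the majority label (``majority``)."""
    present = [m for m in metric_labels if m in SEVERITY]
    if not present:
        return "missing"
    if mode == "worst":
        return max(present, key=lambda m: SEVERITY[m])
    if mode == "majority":
        counts = {lab: present.count(lab) for lab in set(present)}
        best = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == best]
        return max(tied, key=lambda m: SEVERITY[m])
    raise ValueError(f"unknown aggregation mode {mode!r}")


def overall(layer_labels: list[str]) -> str:
    """Damaging in any layer → damaging; benign in every layer → benign;
    otherwise VUS."""
    present = [m for m in layer_labels if m in SEVERITY]
    if not present:
        raise ValueError("no layer labels")
    if "damaging" in present:
        return "damaging"
    if all(m == "benign" for m in present):
        return "benign"
    return "VUS"


def build_ledger(
    score_table: ScoreTable,
    external_layer_labels: pd.DataFrame | None = None,
    layer_mode: str = "worst",
    floor: float = 1e-6,
) -> ImpactLedger:
    """Full classification ledger: per-metric labels, per-layer collective
    labels (optionally merged with externally supplied layer labels, e.g.
    a sequence-predictor layer), and the overall verdict per variant."""
    thresholds = calibrate(score_table, floor=floor)
    variants = list(score_table.values.index)
    metric_labels = pd.DataFrame(index=variants, columns=score_table.values.columns, dtype=object)
    for metric in score_table.values.columns:
        spec = score_table.metrics[metric]
        for variant in variants:
            metric_labels.loc[variant, metric] = label_metric(
                score_table.values.loc[variant, metric], thresholds[metric], spec
            )
    layers_present = []
    for layer in LAYERS:
        if any(score_table.metrics[m].layer == layer for m in score_table.values.columns):
            layers_present.append(layer)
        elif external_layer_labels is not None and layer in external_layer_labels.columns:
            layers_present.append(layer)
    layer_labels = pd.DataFrame(index=variants, columns=layers_present, dtype=object)
    for layer in layers_present:
        metrics_in_layer = [
            m for m in score_table.values.columns if score_table.metrics[m].layer == layer
        ]
        for variant in variants:
            labels = [metric_labels.loc[variant, m] for m in metrics_in_layer]
            if external_layer_labels is not None and layer in external_layer_labels.columns:
                ext = external_layer_labels.loc[variant, layer]
                if isinstance(ext, str) and ext in SEVERITY:
                    labels.append(ext)
            layer_labels.loc[variant, layer] = label_layer(labels, mode=layer_mode)
    overall_labels = pd.Series(
        {v: overall([layer_labels.loc[v, l] for l in layers_present]) for v in variants},
        name="overall",
    )
    return ImpactLedger(
        layer_labels=layer_labels,
        overall_labels=overall_labels,
        metric_labels=metric_labels,
        calibration=thresholds,
        roles=dict(score_table.roles),
    )
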