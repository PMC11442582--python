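"""Qualitative model-validation harness.

Operationalises the study's visual validation logic as five explicit
checks between day-sampled group summaries (synthetic or user-supplied)
and the model's noiseless marker curves:

* ``transient``   — responder markers rise clearly above the healthy-control
                    band at a non-final timepoint wherever the model
                    predicts a clear effect;
* ``resolution``  — every marker's final-day group mean is back inside the
                    control band;
* ``senescence_decline`` — the senescence marker's group means never
                    increase after their peak day;
* ``dose_ordering`` — at the peak day, responder marker means are ordered
                    severe >= moderate >= mild (5% relative slack);
* ``codirection`` — the sign of the early-to-mid-timepoint change agrees
                    between model curve and data.

"Comparable to healthy controls" has no stated quantitative criterion, so
the band rules here are this package's own operationalisation: transparent,
deterministic, and tuned to the N = 3-5 / CV ~ 0.2-0.3 sampling regime the
generator emulates (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import MarkerMap, SyntheticDataset, summarize

__all__ = ["CompareConfig", "ValidationReport", "qualitative_checks", "validate_dataset"]

PASS = "pass"
FAIL = "fail"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class CompareConfig:
    """Thresholds of the validation checks.

    ``k_transient`` scales the control-band width a transient must exceed.
    Final-day resolution is judged on the log scale (fold changes are
    right-skewed): a marker fails only if its final-day mean deviates from
    the control mean by more than ``resolve_fold``-fold AND by more than
    ``k_resolve`` combined standard errors — both practical and statistical
    significance, so an estimated control band cannot fail clean data.
    ``ordering_slack`` is the relative slack on dose ordering (N = 3-5
    group means make strict ordering brittle);
    ``min_effect`` is the minimum model-predicted fold change for the
    transient check to be evaluable, and ``min_trend`` the minimum
    model-predicted day-to-day change for the co-direction check.
    """

    control_group: str = "control"
    dose_order: tuple[str, ...] = ("severe", "moderate", "mild")
    senescence_markers: tuple[str, ...] = ("p21",)
    k_transient: float = 2.0
    k_resolve: float = 4.0
    resolve_fold: float = 1.75
    ordering_slack: float = 0.05
    min_effect: float = 2.0
    min_trend: float = 0.25
    k_trend: float = 2.0


@dataclass
class ValidationReport:
    records: pd.DataFrame  # check, marker, group, status, evidence

    @property
    def overall_pass(self) -> bool:
        return not (self.records["status"] == FAIL).any()

    def failures(self) -> pd.DataFrame:
        return self.records[self.records["status"] == FAIL]

    def by_check(self) -> pd.DataFrame:
        return (
            self.records.groupby(["check", "status"]).size().unstack(fill_value=0)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "overall_pass": self.overall_pass,
                "checks": self.records.to_dict("records"),
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = [f"overall: {'PASS' if self.overall_pass else 'FAIL'}"]
        for (check, status), n in (
            self.records.groupby(["check", "status"]).size().items()
        ):
            lines.append(f"  {check:>18s}  {status:<13s} {n:3d}")
        return "\n".join(lines)


def _lookup(summaries: pd.DataFrame, group: str, day, marker: str):
    row = summaries[
        (summaries["group"] == group)
        & (summaries["day"] == day)
        & (summaries["marker"] == marker)
    ]
    return None if row.empty else row.iloc[0]


def qualitative_checks(
    summaries: pd.DataFrame,
    curves: pd.DataFrame,
    config: CompareConfig | None = None,
    marker_map: MarkerMap | None = None,
) -> ValidationReport:
    """Run all validation checks on group summaries against model curves.

    ``summaries`` needs columns (group, day, marker, mean, sem, n) as
    produced by :func:`senoliv.synthetic.summarize`; ``curves`` needs
    (group, day, marker, value) — the model's noiseless marker predictions
    at the sampled days.  Missing groups or days make individual checks
    ``not_evaluable``, never raise.
    """
    cfg = config or CompareConfig()
    sen_markers = set(cfg.senescence_markers)
    if marker_map is not None:
        sen_markers |= {m for m in marker_map.names if marker_map.variable(m) == "T"}

    days = sorted(summaries["day"].unique())
    markers = list(dict.fromkeys(summaries["marker"]))
    dose_groups = [g for g in dict.fromkeys(summaries["group"]) if g != cfg.control_group]
    final_day = days[-1]

    # Healthy-control band, pooled across days (the study plots one band).
    ctrl = summaries[summaries["group"] == cfg.control_group]
    ctrl_stats: dict[str, tuple[float, float]] = {}
    for m in markers:
        cm = ctrl[ctrl["marker"] == m]
        if cm.empty:
            ctrl_stats[m] = (1.0, 0.0)
        else:
            n_tot = cm["n"].sum()
            pooled_sd = np.sqrt(np.average((cm["sem"] * np.sqrt(cm["n"])) ** 2, weights=cm["n"]))
            ctrl_stats[m] = (float(np.average(cm["mean"], weights=cm["n"])),
                             float(pooled_sd / np.sqrt(n_tot)))

    rows: list[dict] = []

    def emit(check: str, marker: str, group: str, status: str, evidence: str) -> None:
        rows.append(
            {"check": check, "marker": marker, "group": group, "status": status,
             "evidence": evidence}
        )

    def curve_at(group: str, day, marker: str) -> float | None:
        row = curves[
            (curves["group"] == group) & (curves["day"] == day) & (curves["marker"] == marker)
        ]
        return None if row.empty else float(row["value"].iloc[0])

    # C-transient: rise above the control band at a non-final day.
    for m in markers:
        if m in sen_markers:
            continue
        base, base_sem = ctrl_stats[m]
        for g in dose_groups:
            model_vals = [curve_at(g, d, m) for d in days[:-1]]
            model_vals = [v for v in model_vals if v is not None]
            if not model_vals or max(model_vals) < cfg.min_effect:
                emit("transient", m, g, NOT_EVALUABLE,
                     "model predicts no clear transient for this marker/group")
                continue
            obs = [_lookup(summaries, g, d, m) for d in days[:-1]]
            obs = [o for o in obs if o is not None]
            if not obs:
                emit("transient", m, g, NOT_EVALUABLE, "no non-final-day data")
                continue
            band = base + cfg.k_transient * base_sem
            peak = max(o["mean"] for o in obs)
            status = PASS if peak > band else FAIL
            emit("transient", m, g, status, f"peak mean {peak:.3g} vs band {band:.3g}")

    # C-resolution: final-day mean back at the control level.  Judged on
    # the log scale via the delta method; failure needs the deviation to be
    # both larger than resolve_fold-fold and k_resolve standard errors.
    for m in markers:
        base, base_sem = ctrl_stats[m]
        for g in dose_groups:
            o = _lookup(summaries, g, final_day, m)
            if o is None:
                emit("resolution", m, g, NOT_EVALUABLE, f"no day-{final_day} data")
                continue
            mean_g = float(o["mean"])
            if mean_g <= 0 or base <= 0:
                emit("resolution", m, g, FAIL, f"non-positive mean {mean_g:.3g}")
                continue
            sem_g = float(o["sem"]) if np.isfinite(o["sem"]) else 0.0
            dev = abs(np.log(mean_g) - np.log(base))
            se = float(np.hypot(sem_g / mean_g, base_sem / base))
            resolved = dev <= max(cfg.k_resolve * se, np.log(cfg.resolve_fold))
            emit("resolution", m, g, PASS if resolved else FAIL,
                 f"{mean_g:.3g} vs control {base:.3g} "
                 f"({np.exp(dev):.2f}-fold, {dev / se if se > 0 else np.inf:.1f} SE)")

    # C-senescence-decline: means non-increasing after their peak day.
    for m in markers:
        if m not in sen_markers:
            continue
        for g in dose_groups:
            series = [
                (d, _lookup(summaries, g, d, m)) for d in days
            ]
            series = [(d, o) for d, o in series if o is not None]
            if len(series) < 2:
                emit("senescence_decline", m, g, NOT_EVALUABLE, "fewer than two days")
                continue
            means = [float(o["mean"]) for _, o in series]
            peak_i = int(np.argmax(means))
            tail = means[peak_i:]
            ok = all(b <= a * (1 + cfg.ordering_slack) for a, b in zip(tail, tail[1:]))
            status = PASS if ok else FAIL
            emit("senescence_decline", m, g, status,
                 "means " + " -> ".join(f"{v:.3g}" for v in means))

    # C-dose-ordering at the model peak day, responder markers only: the
    # senescent pool itself clears faster at higher doses, so its ordering
    # at the sampled days is clearance- not dose-dominated.
    order = [g for g in cfg.dose_order if g in dose_groups]
    for m in markers:
        if m in sen_markers:
            continue
        if len(order) < 2:
            emit("dose_ordering", m, "all", NOT_EVALUABLE, "fewer than two dose groups")
            continue
        ref = order[0]
        model_series = [(d, curve_at(ref, d, m)) for d in days]
        model_series = [(d, v) for d, v in model_series if v is not None]
        peak_day = max(model_series, key=lambda dv: dv[1])[0] if model_series else days[0]
        obs = [_lookup(summaries, g, peak_day, m) for g in order]
        if any(o is None for o in obs):
            emit("dose_ordering", m, "all", NOT_EVALUABLE, f"missing day-{peak_day} data")
            continue
        means = [float(o["mean"]) for o in obs]
        ok = all(a >= b * (1 - cfg.ordering_slack) for a, b in zip(means, means[1:]))
        status = PASS if ok else FAIL
        emit("dose_ordering", m, "all", status,
             f"day {peak_day}: " + " >= ".join(f"{g}:{v:.3g}" for g, v in zip(order, means)))

    # C-codirection: sign of the (day1 -> day2) change matches the model.
    d0 = days[0]
    d1 = days[1] if len(days) > 1 else days[0]
    for m in markers:
        for g in dose_groups:
            mv0, mv1 = curve_at(g, d0, m), curve_at(g, d1, m)
            if mv0 is None or mv1 is None or abs(mv1 - mv0) < cfg.min_trend:
                emit("codirection", m, g, NOT_EVALUABLE,
                     "model predicts no clear trend between the first two days")
                continue
            o0, o1 = _lookup(summaries, g, d0, m), _lookup(summaries, g, d1, m)
            if o0 is None or o1 is None:
                emit("codirection", m, g, NOT_EVALUABLE, "missing data at early days")
                continue
            data_delta = float(o1["mean"]) - float(o0["mean"])
            se = float(np.hypot(o0["sem"], o1["sem"]))
            same_sign = np.sign(data_delta) == np.sign(mv1 - mv0)
            within_noise = abs(data_delta) <= cfg.k_trend * se
            status = PASS if (same_sign or within_noise) else FAIL
            emit("codirection", m, g, status,
                 f"model {mv1 - mv0:+.3g}, data {data_delta:+.3g} (SE {se:.3g})")

    return ValidationReport(records=pd.DataFrame(rows))


def validate_dataset(
    dataset: SyntheticDataset, config: CompareConfig | None = None
) -> ValidationReport:
    """Round-trip validation of a generated dataset against its own model."""
    return qualitative_checks(
        summarize(dataset), dataset.curves, config=config, marker_map=dataset.marker_map
    )
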