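"""Deconvolution of pooled readouts into candidate strains and anomaly flags.

The decoder works under the *union model* of group testing: a batch shows
activity on a substrate iff at least one of its members is active, so the set
of active batches (the hit set) is the union of the active strains' batch
signatures.  Candidate generation inverts this: every strain set (up to a
stated size) whose combined signature equals the hit set is a consistent
explanation.

Tandem chemistry breaks the union model — a strain that *destroys* the
product makes its batches look less active, not more.  Such situations leave
fingerprints that are screened for separately: a product fraction that falls
between sampling times, and pooled assays diverging from their single-ketone
controls.  Flagged batches feed a suspicion channel (strains best placed to
explain the anomaly) that is kept distinct from the hit-based candidates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd

from .design import AssayPlan, PoolDesign, assay_count

__all__ = [
    "HitPattern",
    "Anomaly",
    "CandidateReport",
    "IncompleteDataError",
    "call_hits",
    "candidates",
    "flag_anomalies",
    "suspect_strains",
    "plan_confirmation",
]

logger = logging.getLogger(__name__)


class IncompleteDataError(ValueError):
    """Readouts do not cover every batch of the design at the requested time."""


@dataclass(frozen=True)
class HitPattern:
    """Active batches for one substrate at one sampling time."""

    substrate: str
    active_batches: frozenset[str]
    scores: dict[str, float]
    threshold: float
    timepoint_used: float


@dataclass(frozen=True)
class Anomaly:
    batch: str
    substrate: str
    type: str  # "non_monotone_product" | "control_assay_divergence"
    evidence: dict[str, float]


@dataclass(frozen=True)
class CandidateReport:
    """Decoding result for one substrate channel."""

    substrate: str
    hit_set: frozenset[str]
    candidate_sets: tuple[tuple[str, ...], ...]
    unique: bool
    anomalies: tuple[Anomaly, ...] = ()
    confirmation_plan: tuple[str, ...] = ()
    assay_accounting: AssayPlan | None = None
    explanation: str = ""

    @property
    def candidate_strains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for cs in self.candidate_sets:
            for s in cs:
                if s not in seen:
                    seen.append(s)
        return tuple(sorted(seen))


def call_hits(
    readouts: pd.DataFrame,
    design: PoolDesign,
    threshold: float = 0.5,
    timepoint: float = 24.0,
    mode: str = "pooled",
) -> dict[str, HitPattern]:
    """Threshold batch conversions into hit patterns, one per substrate.

    A batch is active on a substrate iff its conversion at ``timepoint`` (in
    the given mode) is at least ``threshold``.  All design batches must be
    present for every substrate at that time point.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    rows = readouts[
        (readouts["mode"] == mode) & (readouts["time_h"] == timepoint)
    ]
    patterns: dict[str, HitPattern] = {}
    for substrate, grp in rows.groupby("substrate"):
        scores = (
            grp.set_index("batch_or_strain")["conversion"].astype(float).to_dict()
        )
        missing = [b for b in design.batch_ids if b not in scores]
        if missing:
            raise IncompleteDataError(
                f"substrate {substrate!r} at t={timepoint}: no readout for "
                f"batch(es) {missing}"
            )
        active = frozenset(
            b for b in design.batch_ids if scores[b] >= threshold
        )
        patterns[str(substrate)] = HitPattern(
            substrate=str(substrate),
            active_batches=active,
            scores={b: scores[b] for b in design.batch_ids},
            threshold=threshold,
            timepoint_used=float(timepoint),
        )
    if not patterns:
        raise IncompleteDataError(
            f"no rows in mode {mode!r} at t={timepoint}"
        )
    return patterns


def candidates(
    design: PoolDesign, hits: HitPattern, max_actives: int = 1
) -> CandidateReport:
    """All strain sets of size <= ``max_actives`` whose signatures union to the hit set.

    All consistent sets are reported (a superset of a consistent set is
    itself a consistent, if unparsimonious, explanation); minimal sets come
    first, ties broken lexically by strain id.  An empty hit set decodes to "no active strain" (one empty candidate set,
    reported unique).  A non-empty hit set with no consistent explanation
    yields an explained empty report — the readouts then contradict the
    union model (noise near threshold, or product-destroying tandem
    activity).
    """
    if max_actives < 1:
        raise ValueError("max_actives must be >= 1")
    unknown = hits.active_batches - set(design.batch_ids)
    if unknown:
        raise ValueError(f"hit batches {sorted(unknown)} not in design")
    H = hits.active_batches
    if not H:
        return CandidateReport(
            substrate=hits.substrate,
            hit_set=H,
            candidate_sets=((),),
            unique=True,
            explanation="no active batches: no strain implicated",
        )
    sigs = design.signatures()
    # only strains whose signature is inside H can be part of an exact union
    feasible = sorted(s for s in design.strain_ids if sigs[s] <= H)
    found: list[tuple[str, ...]] = []
    for r in range(1, max_actives + 1):
        for subset in itertools.combinations(feasible, r):
            union = frozenset().union(*(sigs[s] for s in subset))
            if union == H:
                found.append(subset)
    found.sort(key=lambda cs: (len(cs), cs))
    unique = len(found) == 1 and len(found[0]) == 1
    strains = tuple(
        sorted({s for cs in found for s in cs})
    )
    return CandidateReport(
        substrate=hits.substrate,
        hit_set=H,
        candidate_sets=tuple(found),
        unique=unique,
        confirmation_plan=() if unique else strains,
        explanation=(
            ""
            if found
            else "hit set is not a union of <= "
            f"{max_actives} signatures; suspect noise near threshold or "
            "tandem (product-destroying) activity"
        ),
    )


def flag_anomalies(
    readouts: pd.DataFrame,
    product_drop_margin: float = 0.10,
    divergence_margin: float = 0.20,
) -> list[Anomaly]:
    """Screen readouts for the two fingerprints of non-union chemistry.

    non_monotone_product
        Within one (batch, substrate, mode, aeration) series, the product
        fraction at a later sampling time falls below an earlier one by more
        than ``product_drop_margin`` (absolute).  For ketone incubations the
        conversion *is* the product (alcohol) fraction, and a genuine drop
        means the product is being destroyed — classic
        reduction-then-oxidation.  Needs >= 2 time points; otherwise the
        check is skipped with a logged notice.
    control_assay_divergence
        A pooled (mixture) assay differs from its single-ketone control at
        the same time by more than ``divergence_margin`` (absolute
        conversion) — a substrate-interaction effect the union model cannot
        express.
    """
    anomalies: list[Anomaly] = []

    for (batch, substrate, mode, aeration), grp in readouts.groupby(
        ["batch_or_strain", "substrate", "mode", "aeration"]
    ):
        grp = grp.sort_values("time_h")
        if len(grp) < 2:
            logger.info(
                "single time point for %s/%s (%s): non-monotone check skipped",
                batch, substrate, mode,
            )
            continue
        conv = grp["conversion"].to_numpy()
        t = grp["time_h"].to_numpy()
        peak = conv[0]
        peak_t = t[0]
        for ti, ci in zip(t[1:], conv[1:]):
            if peak - ci > product_drop_margin:
                anomalies.append(
                    Anomaly(
                        batch=str(batch),
                        substrate=str(substrate),
                        type="non_monotone_product",
                        evidence={
                            "t_early_h": float(peak_t),
                            "product_early": float(peak),
                            "t_late_h": float(ti),
                            "product_late": float(ci),
                        },
                    )
                )
                break
            if ci > peak:
                peak, peak_t = ci, ti

    pooled = readouts[readouts["mode"] == "pooled"]
    control = readouts[readouts["mode"] == "control"]
    if not pooled.empty and not control.empty:
        merged = pooled.merge(
            control,
            on=["batch_or_strain", "substrate", "time_h", "aeration"],
            suffixes=("_assay", "_control"),
        )
        for _, row in merged.iterrows():
            gap = abs(row["conversion_control"] - row["conversion_assay"])
            if gap > divergence_margin:
                anomalies.append(
                    Anomaly(
                        batch=str(row["batch_or_strain"]),
                        substrate=str(row["substrate"]),
                        type="control_assay_divergence",
                        evidence={
                            "time_h": float(row["time_h"]),
                            "control": float(row["conversion_control"]),
                            "assay": float(row["conversion_assay"]),
                        },
                    )
                )
    return anomalies


def suspect_strains(
    design: PoolDesign, anomalies: list[Anomaly]
) -> dict[str, tuple[str, ...]]:
    """Strains best placed to explain each substrate's anomalous batches.

    For each substrate with flagged batches, prefers strains whose signature
    is *exactly* the flagged set (one agent explains every anomaly and
    nothing else); failing that, any strain confined to the flagged batches.
    This is a suspicion channel, deliberately separate from
    hit-based candidates: an anomalous batch may simultaneously have been
    excluded as a reducer and still harbor the product-destroying strain.
    """
    out: dict[str, tuple[str, ...]] = {}
    sigs = design.signatures()
    by_substrate: dict[str, set[str]] = {}
    for a in anomalies:
        if a.batch in design.batch_ids:
            by_substrate.setdefault(a.substrate, set()).add(a.batch)
    for substrate, flagged in by_substrate.items():
        everywhere = [
            s for s in design.strain_ids
            if flagged <= sigs[s] and sigs[s] <= flagged
        ]
        if everywhere:
            out[substrate] = tuple(sorted(everywhere))
            continue
        partial = [s for s in design.strain_ids if sigs[s] <= flagged]
        out[substrate] = tuple(sorted(partial))
    return out


def plan_confirmation(
    report: CandidateReport,
    design: PoolDesign,
    n_substrates: int = 1,
    n_substrate_mixtures: int = 1,
) -> AssayPlan:
    """Individual-assay plan resolving a candidate report, with accounting.

    One individual confirmatory assay per unresolved candidate strain; a
    unique candidate needs none.  If decoding failed (non-empty hit set, no
    consistent candidate set), the fallback plan covers every strain of the
    implicated batches — exhaustive by construction — and a warning is
    logged.  The returned plan totals the pooled round plus confirmations
    against conventional one-strain-one-substrate screening.
    """
    if report.unique or not report.hit_set:
        n_conf = 0
    elif report.candidate_sets:
        n_conf = len(report.candidate_strains)
    else:
        members = sorted(
            {s for b in report.hit_set for s in design.members(b)}
        )
        logger.warning(
            "no consistent candidate set for %s; falling back to all %d "
            "strains of batches %s",
            report.substrate, len(members), sorted(report.hit_set),
        )
        n_conf = len(members)
    return assay_count(
        design,
        n_substrate_mixtures=n_substrate_mixtures,
        n_substrates=n_substrates,
        n_confirmations=n_conf,
    )
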