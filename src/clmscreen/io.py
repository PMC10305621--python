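"""File formats, run configuration, and the end-to-end study runner.

Conventions: CSV is comma-separated UTF-8 with a header row and dot
decimals.  Conversions and ee are stored as fractions everywhere;
percentages appear only in rendered reports.  Design matrices are written
with a ``strain_id`` column followed by one 0/1 column per batch.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import stereochem
from .decode import call_hits, candidates, flag_anomalies, plan_confirmation, suspect_strains
from .design import PoolDesign, assay_count
from .synthetic_data import READOUT_COLUMNS, make_study_fixture, simulate_assay, simulate_study

__all__ = [
    "RunConfig",
    "write_design_csv",
    "read_design_csv",
    "write_readouts_csv",
    "read_readouts_csv",
    "run_study",
]


class SchemaError(ValueError):
    """A file violated the expected schema; message names the offending row."""


# ---------------------------------------------------------------------------
# design matrices

def write_design_csv(design: PoolDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        design.incidence, index=list(design.strain_ids),
        columns=list(design.batch_ids),
    )
    df.index.name = "strain_id"
    df.to_csv(path)


def read_design_csv(path: str | Path) -> PoolDesign:
    """Parse a design matrix CSV; round-trips with :func:`write_design_csv`."""
    df = pd.read_csv(path, index_col="strain_id")
    M = df.to_numpy()
    bad = np.argwhere(~np.isin(M, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise SchemaError(
            f"{path}: row {i + 2} (strain {df.index[i]!r}): entry "
            f"{M[i, j]!r} is not 0/1"
        )
    col = M.sum(axis=0)
    if not (col == col[0]).all():
        raise SchemaError(f"{path}: batch sizes differ: {col.tolist()}")
    return PoolDesign(
        n_strains=df.shape[0],
        n_batches=df.shape[1],
        incidence=M.astype(int),
        pool_size=int(col[0]),
        strain_ids=tuple(str(s) for s in df.index),
        batch_ids=tuple(str(b) for b in df.columns),
    )


# ---------------------------------------------------------------------------
# readout tables

def write_readouts_csv(readouts: pd.DataFrame, path: str | Path) -> None:
    readouts.loc[:, list(READOUT_COLUMNS)].to_csv(path, index=False)


def read_readouts_csv(path: str | Path) -> pd.DataFrame:
    """Parse and validate a tidy readout table.

    Raises :class:`SchemaError` naming the first offending row (1-based file
    line numbers, header = line 1) for missing columns, conversions outside
    [0, 1], ee outside [-1, 1] (nan allowed: ee is undefined without
    alcohol), or bad mode/aeration labels.
    """
    df = pd.read_csv(path)
    missing = [c for c in READOUT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for i, row in df.iterrows():
        line = int(i) + 2
        c = row["conversion"]
        if not (0.0 <= c <= 1.0):
            raise SchemaError(f"{path}: line {line}: conversion {c} not in [0, 1]")
        ee = row["alcohol_ee"]
        if not (math.isnan(ee) or -1.0 <= ee <= 1.0):
            raise SchemaError(f"{path}: line {line}: ee {ee} not in [-1, 1]")
        if row["aeration"] not in ("aerobic", "anaerobic"):
            raise SchemaError(
                f"{path}: line {line}: aeration {row['aeration']!r} invalid"
            )
        if row["mode"] not in ("pooled", "control", "individual"):
            raise SchemaError(f"{path}: line {line}: mode {row['mode']!r} invalid")
        if row["time_h"] < 0:
            raise SchemaError(f"{path}: line {line}: negative time {row['time_h']}")
    return df


# ---------------------------------------------------------------------------
# run configuration

class RunConfig(BaseModel):
    """Validated knobs for an end-to-end study run."""

    seed: int = 0
    threshold: float = Field(0.5, gt=0.0, lt=1.0)
    product_drop_margin: float = Field(0.10, gt=0.0, lt=1.0)
    divergence_margin: float = Field(0.20, gt=0.0, lt=1.0)
    timepoints: list[float] = Field(default_factory=lambda: [4.0, 24.0])
    call_timepoint: float = 24.0
    noise_sd: float = Field(0.03, ge=0.0)
    max_actives: int = Field(1, ge=1, le=3)
    batch_b_mechanism: str = "oxidation"
    design_path: str | None = None
    readouts_path: str | None = None
    report_path: str | None = None

    @field_validator("timepoints")
    @classmethod
    def _sorted_nonempty(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("timepoints must be non-empty")
        if sorted(v) != v:
            raise ValueError("timepoints must be sorted")
        if v[0] < 0:
            raise ValueError("timepoints must be >= 0")
        return v

    @field_validator("batch_b_mechanism")
    @classmethod
    def _mech(cls, v: str) -> str:
        if v not in ("oxidation", "inhibition"):
            raise ValueError("batch_b_mechanism must be 'oxidation' or 'inhibition'")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (output paths excluded)."""
        payload = self.model_dump(
            exclude={"design_path", "readouts_path", "report_path"}
        )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# end-to-end runner

def _pct(x: float) -> float:
    return round(100.0 * x, 1)


def run_study(config: RunConfig) -> dict[str, Any]:
    """Simulate and decode the full two-library screen; return a report bundle.

    Stages: study fixture (designs + ground-truth kinetics) → pooled/control
    simulation at the configured time points → hit calling per substrate →
    candidate generation → anomaly screening and suspicion channel →
    confirmatory planning and assay accounting → redox follow-up on the
    suspected oxidizer (alcohol incubation under both aerations and the
    oxidation-only yield bound).  Deterministic under ``config.seed``; the
    returned dict is JSON-serializable with sorted keys.
    """
    fixture = make_study_fixture(batch_b_mechanism=config.batch_b_mechanism)
    readouts = simulate_study(
        fixture,
        times=config.timepoints,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    if config.readouts_path:
        write_readouts_csv(readouts, config.readouts_path)

    report: dict[str, Any] = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "batch_b_mechanism": config.batch_b_mechanism,
        "channels": {},
    }
    anomalies = flag_anomalies(
        readouts,
        product_drop_margin=config.product_drop_margin,
        divergence_margin=config.divergence_margin,
    )
    n_confirmations_total = 0
    pooled_total = 0
    candidate_strains: set[str] = set()
    for channel in fixture.mixtures:
        design = fixture.design_for(channel)
        chan_rows = readouts[readouts["substrate"].isin(channel.substrates)]
        batch_rows = chan_rows[chan_rows["batch_or_strain"].isin(design.batch_ids)]
        hits = call_hits(
            batch_rows, design,
            threshold=config.threshold, timepoint=config.call_timepoint,
        )
        chan_anoms = [
            a for a in anomalies
            if a.substrate in channel.substrates and a.batch in design.batch_ids
        ]
        suspicion = suspect_strains(design, chan_anoms)
        chan_report: dict[str, Any] = {}
        for substrate, hp in hits.items():
            rep = candidates(design, hp, max_actives=config.max_actives)
            plan = plan_confirmation(rep, design, n_substrates=1)
            n_confirmations_total += plan.confirmatory_assays
            candidate_strains.update(rep.candidate_strains)
            chan_report[substrate] = {
                "hit_set": sorted(hp.active_batches),
                "scores_pct": {b: _pct(v) for b, v in hp.scores.items()},
                "candidate_sets": [list(cs) for cs in rep.candidate_sets],
                "unique": rep.unique,
                "confirmation_plan": list(rep.confirmation_plan),
                "anomalies": [asdict(a) for a in chan_anoms if a.substrate == substrate],
                "suspected_strains": list(suspicion.get(substrate, ())),
                "explanation": rep.explanation,
            }
        pooled_total += design.n_batches  # one mixture per channel
        report["channels"][channel.name] = chan_report

    n_strains = fixture.clm1.n_strains + fixture.clm2.n_strains
    n_substrates = len(fixture.substrates)
    report["assay_accounting"] = {
        "pooled_assays": pooled_total,
        "confirmatory_assays": n_confirmations_total,
        "total": pooled_total + n_confirmations_total,
        "conventional": n_strains * n_substrates,
    }

    # Redox follow-up on the oxygen-dependent (S)-oxidizer: incubate the
    # racemic product alcohol with the suspected strain under both aerations.
    oxidizer = fixture.profiles[fixture.truth["oxygen_dependent_S_oxidizer"][0]]
    followup: dict[str, Any] = {"strain": oxidizer.strain_id}
    for aeration in ("aerobic", "anaerobic"):
        df = simulate_assay(
            [oxidizer], "phenylethanol", config.timepoints,
            aeration=aeration, noise_sd=0.0, y0=(0.0, 0.5, 0.5),
        )
        last = df.iloc[-1]
        alcohol_total = 1.0 - float(last["conversion"])
        ee = float(last["alcohol_ee"])
        split = stereochem.split_from_ee(alcohol_total, 0.0 if math.isnan(ee) else ee)
        present, margin = stereochem.infer_reduction_present(split, initial_ee=0.0)
        followup[aeration] = {
            "ketone_pct": _pct(float(last["conversion"])),
            "alcohol_ee_pct": _pct(ee) if not math.isnan(ee) else None,
            "R_fraction_pct": _pct(split.R_fraction),
            "oxidation_only_bound_pct": _pct(
                stereochem.max_R_yield_oxidation_only(0.0)
            ),
            "reduction_inferred": bool(present),
            "margin_pct": _pct(margin),
        }
    report["oxidizer_followup"] = followup

    if config.report_path:
        Path(config.report_path).write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return report
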