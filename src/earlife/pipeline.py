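"""End-to-end orchestration: simulate/ingest -> aggregate -> screen ->
fit -> compare -> permute -> report.

Every stage is seeded from one master seed via spawned child seeds, so
rerunning with the same configuration reproduces every number.  Stage
boundaries are logged with row/participant counts so cohort filters
(e.g. 91 -> 87 for class attendance) are auditable, and a manifest
records seeds, package versions, and input digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviors import (
    CODED_BEHAVIORS,
    MERGE_SOURCES,
    RELIGIOUS_OR_VOLUNTEER,
    behavior_map,
)
from .comparison import SelectionReport, build_and_select
from .data_io import (
    aggregate_counts,
    apply_cohort_filters,
    merge_religious_volunteer,
    pool_strata,
    read_clips,
    read_count_table,
    write_count_table,
)
from .errors import ConfigurationError
from .permutation import permute_and_refit, summarize_permutation
from .reliability import apply_reliability_gate
from .sampler import SamplerConfig
from .synthetic import ProtocolConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    input_mode: str = "synthetic"  # synthetic | clip_file | count_file
    input_path: str | None = None
    participants_path: str | None = None  # required with clip_file mode
    n_participants: int = 91
    seed: int = 0
    output_dir: str = "earlife_output"
    kappa_threshold: float = 0.41
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    n_permutation_runs: int = 100
    permute_all: bool = False  # permute every behavior, not only favored ones
    log_level: str = "INFO"

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "clip_file", "count_file"):
            raise ConfigurationError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode != "synthetic" and not self.input_path:
            raise ConfigurationError(f"{self.input_mode} mode requires input_path")
        if self.seed is None:
            raise ConfigurationError("a master seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sampler = SamplerConfig(**raw.pop("sampler", {}))
        return cls(sampler=sampler, **raw)


#: Reduced settings keeping exploratory pipeline runs fast.
TEST_PROFILE = dict(
    sampler=SamplerConfig(chains=2, draws=500, warmup=500),
    n_permutation_runs=25,
)


def run_descriptives(rows: pd.DataFrame, participants: pd.DataFrame | None = None):
    """Per-behavior distribution of participant occurrence proportions.

    Uses pooled (non-stratified) per-participant counts: mean, SD
    (sample SD), and range of k/n over participants with n > 0, plus
    the proportion of those participants observed to engage at least
    once.
    """
    pooled = pool_strata(rows)
    records = []
    for behavior, sub in pooled.groupby("behavior", sort=False):
        sub = sub[sub["n"] > 0]
        if len(sub) == 0:
            records.append(
                {
                    "behavior": behavior,
                    "n_participants": 0,
                    "mean": np.nan,
                    "sd": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                    "prop_engaged": np.nan,
                }
            )
            continue
        prop = sub["k"].to_numpy() / sub["n"].to_numpy()
        records.append(
            {
                "behavior": behavior,
                "n_participants": int(len(sub)),
                "mean": float(prop.mean()),
                "sd": float(prop.std(ddof=1)) if len(prop) > 1 else 0.0,
                "min": float(prop.min()),
                "max": float(prop.max()),
                "prop_engaged": float((sub["k"] > 0).mean()),
            }
        )
    return pd.DataFrame(records).set_index("behavior")


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    rows: pd.DataFrame
    participants: pd.DataFrame
    descriptives: pd.DataFrame
    retained: list
    excluded: list
    selection: dict[str, SelectionReport]
    permutation: dict[str, dict]
    manifest: dict


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and persist outputs under ``config.output_dir``."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(
            ("simulate", "selection", "permutation"), ss.spawn(3)
        )
    }
    manifest: dict = {
        "earlife_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "input_mode": config.input_mode,
        "inputs": {},
    }

    # --- stage: ingest or simulate -------------------------------------
    clips = None
    if config.input_mode == "synthetic":
        clips, participants, truth = simulate_study(
            n_participants=config.n_participants, seed=stage_seeds["simulate"]
        )
        logger.info(
            "simulated %d clips for %d participants", len(clips), config.n_participants
        )
    elif config.input_mode == "clip_file":
        clips = read_clips(config.input_path)
        manifest["inputs"][str(config.input_path)] = _digest(config.input_path)
        if not config.participants_path:
            raise ConfigurationError(
                "clip_file mode requires participants_path (trait/sex table)"
            )
        participants = pd.read_csv(config.participants_path)
        manifest["inputs"][str(config.participants_path)] = _digest(
            config.participants_path
        )
    else:
        participants, rows = read_count_table(config.input_path)
        manifest["inputs"][str(config.input_path)] = _digest(config.input_path)

    # --- stage: reliability gate ---------------------------------------
    retained, excluded = apply_reliability_gate(
        list(CODED_BEHAVIORS), threshold=config.kappa_threshold
    )
    logger.info(
        "reliability gate: %d retained, %d excluded", len(retained), len(excluded)
    )

    # --- stage: aggregate ----------------------------------------------
    if clips is not None:
        rows = aggregate_counts(clips, retained, stratify_by_weekend=True)
        rows = merge_religious_volunteer(rows, clips=clips)
    elif RELIGIOUS_OR_VOLUNTEER.name not in set(rows["behavior"]):
        if set(MERGE_SOURCES) <= set(rows["behavior"]):
            rows = merge_religious_volunteer(rows)
    n_before = rows["participant_id"].nunique()
    rows = apply_cohort_filters(rows, participants)
    logger.info(
        "aggregated %d count rows for %d participants (cohort filters applied)",
        len(rows),
        n_before,
    )
    write_count_table(out / "count_table.csv", rows, participants)

    # --- stage: descriptives -------------------------------------------
    descriptives = run_descriptives(rows, participants)
    descriptives.to_csv(out / "descriptives.csv")

    # --- stage: selection ----------------------------------------------
    analysis_specs = [
        b for b in retained if b.name not in MERGE_SOURCES
    ] + [RELIGIOUS_OR_VOLUNTEER]
    bmap = behavior_map(analysis_specs)
    sel_ss = np.random.SeedSequence(stage_seeds["selection"])
    selection: dict[str, SelectionReport] = {}
    for spec, child in zip(analysis_specs, sel_ss.spawn(len(analysis_specs))):
        if spec.name not in set(rows["behavior"]):
            continue
        report = build_and_select(
            spec,
            rows,
            participants,
            config=config.sampler,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        selection[spec.name] = report
        logger.info(
            "selection %s: weight=%.3f slope=%.3f favored=%s",
            spec.name,
            report.focal_weight,
            report.slope_mean,
            report.alhb_favored,
        )
    with open(out / "selection.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in selection.items()}, fh, indent=2)

    # --- stage: permutation --------------------------------------------
    perm_ss = np.random.SeedSequence(stage_seeds["permutation"])
    permutation: dict[str, dict] = {}
    targets = [
        name
        for name, rep in selection.items()
        if (rep.alhb_favored or config.permute_all) and not rep.degenerate
    ]
    for name, child in zip(targets, perm_ss.spawn(max(len(targets), 1))):
        rep = selection[name]
        runs = permute_and_refit(
            bmap[name],
            rows,
            participants,
            n_runs=config.n_permutation_runs,
            master_seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            config=config.sampler,
            predictors=rep.focal_predictors,
            reference_predictors=rep.adopted,
        )
        runs.to_csv(out / f"permutation_{name}.csv", index=False)
        permutation[name] = summarize_permutation(
            runs, rep.slope_mean, rep.focal_weight
        )
        logger.info("permutation %s: %s", name, permutation[name])
    with open(out / "permutation.json", "w") as fh:
        json.dump(permutation, fh, indent=2)

    manifest["n_count_rows"] = int(len(rows))
    manifest["n_participants"] = int(participants["participant_id"].nunique())
    manifest["behaviors_retained"] = [b.name for b in retained]
    manifest["behaviors_excluded"] = [b.name for b in excluded]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(
        config=config,
        rows=rows,
        participants=participants,
        descriptives=descriptives,
        retained=retained,
        excluded=excluded,
        selection=selection,
        permutation=permutation,
        manifest=manifest,
    )
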