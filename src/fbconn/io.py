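"""Readers, writers, run configuration and end-to-end pipeline orchestration.

Subject time series come in as delimited text (one file per subject, rows =
time points, header row of component ids).  The pipeline runs:

    read -> w(t) -> filter bank -> observation matrix -> k-means states
         -> fraction rates -> (optional) two-group comparison

Every stage draws its randomness from one root seed (deterministically
split per stage), writes its outputs as delimited text or JSON, and the
whole run is summarized in a manifest sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ComponentTimeSeries,
    SwpcTrajectory,
    WindowSpec,
    pair_labels,
    pair_product_trajectory,
    swpc,
)
from .filterbank import (
    BandFilter,
    FilterDesignSpec,
    apply_filter_bank,
    build_bank,
    design_filter,
    zero_phase_filter,
)
from .states import (
    ObservationMatrix,
    StateModel,
    assemble_observations,
    cluster_states,
    devectorize_fnc,
    fraction_rates,
)
from .groupstats import compare_fraction_rates

logger = logging.getLogger("fbconn")

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_timeseries",
    "write_timeseries",
    "write_trajectory",
    "run_pipeline",
    "highpassed_swpc_scenario",
]

_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(
    path, expected_components: int | None = None, tr_seconds: float = 1.0,
    subject_id: str | None = None,
) -> ComponentTimeSeries:
    """Read one subject's time x component matrix from TSV/CSV.

    The first row must be a header of component ids; every body cell must
    be numeric.  Parse errors name the offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str,
                     skip_blank_lines=True)
    if df.columns.str.match(r"^-?\d").any():
        raise ValueError(f"{path}: first row looks numeric; a header row of component ids is required")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax())
            raise ValueError(
                f"{path}: non-numeric or missing value at data row {row + 1}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    if expected_components is not None and values.shape[1] != expected_components:
        raise ValueError(
            f"{path}: expected {expected_components} components, found {values.shape[1]}"
        )
    return ComponentTimeSeries(
        values=values,
        tr_seconds=tr_seconds,
        component_ids=list(df.columns),
        subject_id=subject_id or path.stem,
    )


def write_timeseries(X: ComponentTimeSeries, path) -> None:
    path = Path(path)
    pd.DataFrame(X.values, columns=X.component_ids).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_trajectory(traj, path) -> None:
    """Write a trajectory (w or SWPC) as text: time_s column + one column per pair."""
    path = Path(path)
    cols = pair_labels(traj.component_ids)
    df = pd.DataFrame(traj.values, columns=cols)
    df.insert(0, "time_s", traj.times_seconds())
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration; defaults follow the reference analysis
    (TR 2 s, 11-sample window, 10-band Chebyshev-II bank, k=8, 30 k-means
    replicates, q=0.05)."""

    tr_seconds: float
    inputs: list[str] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)
    output_dir: str = "fbc_out"
    window_samples: int = 11
    n_bands: int = 10
    family: str = "chebyshev2"
    stopband_atten_db: float = 30.0
    passband_ripple_db: float = 3.0
    transition_fraction: float = 0.25
    k: int = 8
    replicates: int = 30
    seed: int = 0
    q_level: float = 0.05

    def window(self) -> WindowSpec:
        return WindowSpec.from_window_length(self.window_samples)

    def bank_spec(self) -> FilterDesignSpec:
        return FilterDesignSpec(
            sampling_hz=1.0 / self.tr_seconds,
            n_bands=self.n_bands,
            family=self.family,
            stopband_atten_db=self.stopband_atten_db,
            passband_ripple_db=self.passband_ripple_db,
            transition_fraction=self.transition_fraction,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit given its inputs."""

    config: dict
    version: str
    seeds: dict
    stage_counts: dict
    realized_filters: list
    outputs: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_seeds(root_seed: int) -> dict:
    """Deterministic per-stage integer seeds derived from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    names = ("cluster", "elbow", "simulate", "misc")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full banded-connectivity analysis described by ``config``.

    Writes, under ``config.output_dir``: the designed bank (JSON), per-state
    centroid matrices (TSV), state labels, tidy fraction-rate tables,
    the group comparison (if group labels are given), and the manifest.
    """
    if not config.inputs:
        raise ValueError("run_pipeline: no input files configured")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    win = config.window()
    counts: dict = {}
    outputs: list[str] = []

    # stage: ingest + connectivity-domain transform + band filtering
    bank = build_bank(config.bank_spec())
    bank_path = outdir / "bank.json"
    bank.to_json(bank_path)
    outputs.append(str(bank_path))

    banded = []
    n_components = None
    for p in config.inputs:
        X = read_timeseries(p, expected_components=n_components,
                            tr_seconds=config.tr_seconds)
        n_components = X.n_components
        w = pair_product_trajectory(X, win)
        banded.append(apply_filter_bank(w, bank))
        counts.setdefault("trajectory_samples", {})[X.subject_id] = w.n_samples
    counts["subjects"] = len(banded)
    counts["pairs"] = banded[0].n_pairs

    # stage: observation assembly + clustering
    obs = assemble_observations(banded)
    counts["observations"] = obs.n_rows
    counts["dropped_rows"] = obs.n_dropped
    model = cluster_states(
        obs, k=config.k, replicates=config.replicates, seed=seeds["cluster"]
    )
    comp_ids = banded[0].component_ids
    for s in range(model.k):
        mat = devectorize_fnc(model.centroids[s])
        cpath = outdir / f"state_{s}_centroid.tsv"
        pd.DataFrame(mat, index=comp_ids, columns=comp_ids).to_csv(cpath, sep="\t")
        outputs.append(str(cpath))
    labels_path = outdir / "labels.tsv"
    pd.DataFrame(
        {"subject": obs.subjects, "band": obs.bands, "time": obs.times,
         "state": model.labels}
    ).to_csv(labels_path, sep="\t", index=False)
    outputs.append(str(labels_path))

    # stage: fraction rates
    table = fraction_rates(model, obs)
    for name, df in (("fractions_per_band", table.per_band),
                     ("fractions_overall", table.overall)):
        fpath = outdir / f"{name}.tsv"
        out = df.copy()
        if config.groups:
            out.insert(1, "group", out["subject"].map(config.groups))
        out.to_csv(fpath, sep="\t", index=False)
        outputs.append(str(fpath))

    # stage: group comparison (optional)
    comparison = None
    if config.groups:
        comparison = compare_fraction_rates(
            table, config.groups, scope="overall", q=config.q_level
        )
        cmp_path = outdir / "group_comparison.tsv"
        comparison.table.to_csv(cmp_path, sep="\t", index=False)
        outputs.append(str(cmp_path))

    manifest = RunManifest(
        config=asdict(config),
        version=_VERSION,
        seeds=seeds,
        stage_counts=counts,
        realized_filters=[
            {"band_index": f.band_index, "edges": list(f.passband_edges),
             "order": f.filter_order, **f.realized_specs}
            for f in bank.filters
        ],
        outputs=outputs,
    )
    manifest.to_json(outdir / "manifest.json")
    logger.info("pipeline complete: %d subjects, %d observations, k=%d",
                counts["subjects"], counts["observations"], config.k)
    return manifest


# ---------------------------------------------------------------------------
# High-passed SWPC verification scenario
# ---------------------------------------------------------------------------

def highpassed_swpc_scenario(
    swpc_list: list[SwpcTrajectory],
    cutoffs_hz: list[float],
    k: int = 8,
    replicates: int = 30,
    seed: int | None = None,
    design: FilterDesignSpec | None = None,
) -> dict[float, tuple[StateModel, ObservationMatrix]]:
    """Cluster SWPC trajectories after removing low frequencies.

    For each cutoff (0 means no filtering) the SWPC series of every subject
    are zero-phase high-pass filtered at that cutoff and re-clustered.
    States that only emerge after high-passing corroborate the plausibility
    of band-limited states found by the filter bank.
    """
    if not swpc_list:
        raise ValueError("no SWPC trajectories provided")
    fs = 1.0 / swpc_list[0].tr_seconds
    nyq = fs / 2.0
    results: dict[float, tuple[StateModel, ObservationMatrix]] = {}
    for i, cutoff in enumerate(cutoffs_hz):
        if cutoff < 0 or cutoff >= nyq:
            raise ValueError(f"cutoff {cutoff} Hz outside [0, Nyquist={nyq})")
        if cutoff == 0:
            hp: BandFilter | None = None
        else:
            spec = design or FilterDesignSpec(sampling_hz=fs, n_bands=1)
            hp = design_filter((cutoff, nyq), spec, band_index=1)
        blocks, subj, times = [], [], []
        for traj in swpc_list:
            vals = traj.values
            finite = np.all(np.isfinite(vals), axis=1)
            vals = vals[finite]
            if hp is not None:
                vals = zero_phase_filter(vals, hp, axis=0)
            blocks.append(vals)
            subj.append(np.repeat(traj.subject_id or "subject", vals.shape[0]))
            times.append(np.flatnonzero(finite))
        values = np.vstack(blocks)
        obs = ObservationMatrix(
            values=values,
            subjects=np.concatenate(subj),
            bands=np.zeros(values.shape[0], dtype=int),
            times=np.concatenate(times),
        )
        child = None if seed is None else seed + i
        model = cluster_states(obs, k=k, replicates=replicates, seed=child)
        results[cutoff] = (model, obs)
    return results
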