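"""File formats: WAV input, HDF5 array containers, TSV tables, config.

HDF5 carries the array data (evoked responses, cohorts, models), TSV the
tabular outputs, YAML/JSON the run configuration.  Every run directory
gets a resolved copy of its configuration and a manifest with input
hashes so results are reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EvokedSet
from .features import Waveform
from .synthetic import Cohort, CohortSpec

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_wav",
    "write_evoked",
    "read_evoked",
    "write_cohort",
    "read_cohort_responses",
    "read_annotations",
    "load_config",
    "write_manifest",
]


class SchemaError(ValueError):
    """A file is missing required metadata or is internally inconsistent."""


def read_wav(path, expected_rate: int = 16_000, resample: bool = True) -> Waveform:
    """Read a PCM mono WAV file as a float waveform at 16 kHz.

    Integer PCM is scaled to [-1, 1]; other rates are polyphase
    resampled to ``expected_rate`` unless ``resample`` is off.
    """
    from scipy.io import wavfile
    from scipy.signal import resample_poly

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim != 1:
        raise SchemaError(f"{path}: expected mono WAV, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    data = data.astype(float)
    if rate != expected_rate:
        if not resample:
            raise SchemaError(f"{path}: rate {rate} != {expected_rate}")
        g = np.gcd(int(rate), int(expected_rate))
        data = resample_poly(data, expected_rate // g, rate // g)
        rate = expected_rate
    return Waveform(data, rate)


def write_evoked(path, evoked: EvokedSet) -> None:
    """Write one participant's evoked set to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=evoked.data)
        f.attrs["rate"] = evoked.rate
        f.attrs["onset"] = evoked.onset
        f.create_dataset(
            "stimulus_ids", data=np.array([str(s) for s in evoked.stimulus_ids], dtype="S")
        )


def read_evoked(path) -> EvokedSet:
    """Read and validate an evoked set written by :func:`write_evoked`."""
    with h5py.File(path, "r") as f:
        if "data" not in f or "rate" not in f.attrs or "onset" not in f.attrs:
            raise SchemaError(f"{path}: missing data/rate/onset")
        data = f["data"][()]
        if data.ndim != 3:
            raise SchemaError(f"{path}: data must be (stimulus, sensor, time)")
        rate = float(f.attrs["rate"])
        onset = int(f.attrs["onset"])
        if "stimulus_ids" in f:
            ids = [s.decode() for s in f["stimulus_ids"][()]]
        else:
            raise SchemaError(f"{path}: missing stimulus_ids")
    if len(ids) != data.shape[0]:
        raise SchemaError(f"{path}: {len(ids)} stimulus ids for {data.shape[0]} stimuli")
    if not 0 <= onset < data.shape[2]:
        raise SchemaError(f"{path}: onset {onset} outside time axis")
    return EvokedSet(data, rate, onset, ids)


def write_cohort(h5_path, tsv_path, cohort: Cohort) -> None:
    """Write a simulated cohort: responses to HDF5, participants to TSV."""
    with h5py.File(h5_path, "w") as f:
        data = np.stack([e.data for e in cohort.evoked])
        f.create_dataset("responses", data=data)
        f.attrs["rate"] = cohort.evoked[0].rate
        f.attrs["onset"] = cohort.evoked[0].onset
        f.attrs["deficit_factor"] = cohort.deficit_factor
        f.create_dataset(
            "participant_id",
            data=np.array([p.id for p in cohort.participants], dtype="S"),
        )
        f.create_dataset("group", data=np.array(cohort.groups, dtype="S"))
        env = np.concatenate(cohort.stimuli.envelopes)
        f.create_dataset("envelope_values", data=env)
        f.create_dataset("envelope_lengths", data=cohort.stimuli.n_frames)
    rows = [
        {
            "participant_id": p.id,
            "group": p.group,
            "noise_sd": p.noise_sd,
            "seed": p.seed,
            "early_gain": p.response_function.early_gain,
            "late_gain": p.response_function.late_gain,
        }
        for p in cohort.participants
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_cohort_responses(h5_path):
    """Read a cohort file back as (EvokedSet list, groups, ids, envelopes)."""
    with h5py.File(h5_path, "r") as f:
        for key in ("responses", "participant_id", "group", "envelope_values"):
            if key not in f:
                raise SchemaError(f"{h5_path}: missing {key}")
        data = f["responses"][()]
        rate = float(f.attrs["rate"])
        onset = int(f.attrs["onset"])
        ids = [s.decode() for s in f["participant_id"][()]]
        groups = np.array([s.decode() for s in f["group"][()]])
        env = f["envelope_values"][()]
        lengths = f["envelope_lengths"][()]
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    envelopes = [env[bounds[i] : bounds[i + 1]] for i in range(len(lengths))]
    evoked = [EvokedSet(data[p], rate, onset) for p in range(data.shape[0])]
    return evoked, groups, ids, envelopes


def read_annotations(path) -> pd.DataFrame:
    """Read a time-aligned phoneme table (TSV: word_id, phoneme, start_s, end_s)."""
    df = pd.read_csv(path, sep="\t")
    required = {"word_id", "phoneme", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: needs columns {sorted(required)}")
    return df


@dataclass
class RunConfig:
    """Resolved run configuration; every run writes a copy of it."""

    seed: int = 0
    out_dir: str = "."
    cohort: dict = field(default_factory=dict)
    deficit_factor: float = 0.5
    noise_sd: float = 2.0
    lag_min_ms: float = 20.0
    lag_max_ms: float = 420.0
    lag_step_ms: float = 20.0
    lambda_grid: list = field(default_factory=lambda: [10.0**k for k in range(-3, 7)])
    lambda_mode: str = "once"
    n_permutations: int = 1000
    alpha_cluster: float = 0.05
    group_col: str = "group"

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(**{**self.cohort, "seed": self.seed})

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def load_config(path=None, **overrides) -> RunConfig:
    """Load YAML/JSON config, apply CLI overrides, and validate."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if cfg.lambda_mode not in ("once", "per-split"):
        raise SchemaError("lambda_mode must be 'once' or 'per-split'")
    return cfg


def write_manifest(out_dir, inputs: dict, seed: int) -> None:
    """Record sha256 of every input file plus the master seed."""
    entries = {}
    for name, p in inputs.items():
        p = Path(p)
        entries[name] = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
    Path(out_dir, "manifest.json").write_text(
        json.dumps({"seed": seed, "inputs": entries}, indent=2, sort_keys=True)
    )
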