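"""Reading and writing the on-disk dataset and result formats.

A dataset is a JSON manifest plus one delimited-text signal file per trial
(columns = muscles, header row with muscle names).  The same reader serves
generated data and real recordings exported to this layout.  Result tables
are tidy delimited text written with 6 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .synthetic import RawTrial

__all__ = ["PipelineConfig", "load_manifest", "write_table", "read_table",
           "decomposition_to_json", "decomposition_from_json",
           "export_decomposition_tables"]


def load_manifest(manifest_path: str | Path) -> tuple[list[RawTrial], list[str], float]:
    """Load every trial listed in a dataset manifest.

    Returns (trials, muscle_names, sampling_rate).  Signal files are
    delimited text with one column per muscle; the header must match the
    manifest's muscle list.
    """
    manifest_path = Path(manifest_path)
    try:
        meta = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed manifest {manifest_path}: {e}") from e
    for key in ("sampling_rate", "muscles", "trials"):
        if key not in meta:
            raise ValueError(f"manifest missing required key {key!r}")
    muscles = list(meta["muscles"])
    root = manifest_path.parent
    trials = []
    for entry in meta["trials"]:
        path = root / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"signal file {path} listed in manifest not found")
        df = pd.read_csv(path, sep=None, engine="python")
        if list(df.columns) != muscles:
            raise ValueError(
                f"{path.name}: muscle names {list(df.columns)} do not match "
                f"manifest {muscles}")
        trials.append(RawTrial(
            participant_id=str(entry["participant"]),
            task_id=str(entry["task"]),
            trial_id=int(entry["trial"]),
            signals=df.to_numpy(dtype=float).T,
            sampling_rate=float(meta["sampling_rate"]),
            events=tuple(int(v) for v in entry["events"])))
    return trials, muscles, float(meta["sampling_rate"])


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy result table as TSV with stable 6-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class PipelineConfig:
    """Every tunable of the full pipeline, with study defaults."""

    manifest: str | None = None
    outdir: str = "results"
    # preprocessing
    band: tuple[float, float] = (10.0, 400.0)
    filter_order: int = 4
    lowpass: float = 6.0
    points_per_phase: int = 100
    # factorization
    restarts: int = 50
    max_iter: int = 500
    tol: float = 1e-6
    k_max: int | None = None          # defaults to muscles - 1
    solver: str = "anls"
    # selection
    tvaf_threshold: float = 90.0
    increment_threshold: float = 1.0
    # similarity
    cossim_threshold: float = 0.8
    rmax_threshold: float = 0.9
    alpha: float = 0.01
    max_lag_fraction: float = 0.1
    rmax_on_concatenated: bool = True  # False: trial-averaged 100-point rows
    # seeds
    seed: int = 0
    # optional simulation stage (dict of GeneratorConfig overrides)
    simulate: dict[str, Any] | None = None
    reference_participant: str | None = None

    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        return cfg

    def validate(self, muscles: int | None = None) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("tvaf_threshold",):
            if not 0 < getattr(self, name) < 100:
                raise ValueError(f"{name} must be in (0, 100)")
        if self.increment_threshold < 0:
            raise ValueError("increment_threshold must be >= 0")
        if not 0 < self.cossim_threshold <= 1 or not 0 < self.rmax_threshold <= 1:
            raise ValueError("similarity thresholds must be in (0, 1]")
        if self.restarts < 1 or self.max_iter < 1:
            raise ValueError("restarts and max_iter must be >= 1")
        if self.band[0] <= 0 or self.band[1] <= self.band[0]:
            raise ValueError(f"invalid band edges {self.band}")
        if muscles is not None and self.k_max is not None and self.k_max > muscles - 1:
            raise ValueError(
                f"k_max={self.k_max} exceeds muscles - 1 = {muscles - 1}")

    def to_json(self) -> dict[str, Any]:
        out = {}
        for k, v in vars(self).items():
            out[k] = list(v) if isinstance(v, tuple) else v
        return out


def decomposition_to_json(d, path: str | Path | None = None) -> dict:
    """Serialize a decomposition (matrices row-major with shape metadata)."""
    blob = dict(
        k=d.k, tvaf=d.tvaf, restarts=d.restarts,
        best_restart_seed=d.best_restart_seed, converged=d.converged,
        iterations_used=d.iterations_used, participant_id=d.participant_id,
        task_id=d.task_id,
        W=dict(shape=list(d.W.shape), data=d.W.ravel().tolist()),
        C=dict(shape=list(d.C.shape), data=d.C.ravel().tolist()),
    )
    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(blob))
    return blob


def decomposition_from_json(source: str | Path | dict):
    """Inverse of :func:`decomposition_to_json`."""
    from .factorization import SynergyDecomposition

    blob = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    return SynergyDecomposition(
        W=np.array(blob["W"]["data"]).reshape(blob["W"]["shape"]),
        C=np.array(blob["C"]["data"]).reshape(blob["C"]["shape"]),
        k=blob["k"], tvaf=blob["tvaf"], restarts=blob["restarts"],
        best_restart_seed=blob["best_restart_seed"],
        converged=blob["converged"], iterations_used=blob["iterations_used"],
        participant_id=blob.get("participant_id"), task_id=blob.get("task_id"))


def export_decomposition_tables(d, outdir: str | Path,
                                muscle_names: list[str] | None = None,
                                stem: str = "decomposition") -> tuple[Path, Path]:
    """Write W and C as delimited text (synergies as columns/rows)."""
    outdir = Path(outdir)
    cols = [f"synergy_{j + 1}" for j in range(d.k)]
    w_df = pd.DataFrame(d.W, columns=cols)
    if muscle_names is not None:
        w_df.insert(0, "muscle", muscle_names)
    c_df = pd.DataFrame(d.C.T, columns=cols)
    return (write_table(w_df, outdir / f"{stem}_W.tsv"),
            write_table(c_df, outdir / f"{stem}_C.tsv"))
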