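"""Readers, writers and the reproducible pipeline runner.

Long-format longitudinal tables (``individual_id,group,age,trait,value``),
replicate tables for error estimation, TPS landmark files, YAML configs,
and a pipeline driver that chains smoothing, group-mean removal and the
canalization estimators while writing a manifest sufficient to reproduce
the run.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morpho import LandmarkSet

__all__ = [
    "RunConfig",
    "read_longitudinal_csv",
    "read_replicate_csv",
    "read_tps",
    "write_longitudinal_csv",
    "read_semilandmark_curves",
    "run_pipeline",
]

_REQUIRED_COLS = ("individual_id", "age", "trait", "value")


@dataclass
class RunConfig:
    """Settings of one reproducible analysis run."""

    input_path: str
    out_dir: str
    trait: str | None = None
    grid_start: float = 2.0
    grid_stop: float = 17.0
    grid_step: float = 1.0
    window: float = 2.5
    group_column: str | None = None
    error_replicates: str | None = None
    multivariate: bool = False
    pls_k: int | None = None
    age_a: float | None = None
    age_b: float | None = None
    seed: int | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid step must be > 0")
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.error_replicates and not Path(self.error_replicates).exists():
            raise FileNotFoundError(self.error_replicates)

    @property
    def grid_ages(self) -> np.ndarray:
        # inclusive of both endpoints
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step))
        return self.grid_start + self.grid_step * np.arange(n + 1)


def read_longitudinal_csv(path) -> pd.DataFrame:
    """Read a long-format longitudinal table, validating types and uniqueness.

    Requires columns ``individual_id, age, trait, value`` (``group`` and any
    extra columns are carried along as metadata).  Non-numeric ages/values
    and duplicated (individual, age, trait) records raise errors naming the
    offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("age", "value"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric '{col}' in data row(s) {list(bad + 2)[:10]}"
            )
        df[col] = converted
    if not np.all(np.isfinite(df["age"].to_numpy(dtype=float))):
        raise ValueError(f"{path}: ages must be finite")
    dupes = df.duplicated(subset=["individual_id", "age", "trait"], keep=False)
    if dupes.any():
        rows = list(df.index[dupes] + 2)  # 1-based, plus header line
        raise ValueError(
            f"{path}: duplicate (individual_id, age, trait) record(s) at "
            f"file row(s) {rows[:10]}"
        )
    return df


def write_longitudinal_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_replicate_csv(path) -> pd.DataFrame:
    """Read a replicate-measurement table `individual_id,age,replicate,trait,value`."""
    df = pd.read_csv(path)
    required = ("individual_id", "age", "replicate", "value")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df["age"] = pd.to_numeric(df["age"])
    df["value"] = pd.to_numeric(df["value"])
    return df


def read_tps(path) -> LandmarkSet:
    """Read 2-D landmark configurations from a TPS file.

    Supports ``LM=``, ``ID=`` and ``SCALE=`` records; the scale factor, when
    present, multiplies that specimen's coordinates (pixel-to-unit
    conversion).  A mismatch between the declared landmark count and the
    coordinate lines raises an error naming the specimen.
    """
    specimens: list[np.ndarray] = []
    ids: list[str] = []
    current: list[list[float]] = []
    expected = None
    scale = None
    spec_index = 0

    def finish() -> None:
        nonlocal current, expected, scale, spec_index
        if expected is None:
            return
        if len(current) != expected:
            raise ValueError(
                f"TPS specimen {spec_index}: LM={expected} but "
                f"{len(current)} coordinate line(s)"
            )
        arr = np.asarray(current, dtype=float)
        if scale is not None:
            arr = arr * scale
        specimens.append(arr)
        if len(ids) < len(specimens):
            ids.append(f"spec{len(specimens) - 1:04d}")
        current, expected, scale = [], None, None
        spec_index += 1

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                finish()
                expected = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                ids.append(line.split("=", 1)[1].strip())
            elif upper.startswith("SCALE="):
                scale = float(line.split("=", 1)[1])
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                continue  # unknown record type (IMAGE=, COMMENT=, ...)
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"TPS specimen {spec_index}: bad coordinate line {line!r}")
                current.append([float(parts[0]), float(parts[1])])
    finish()
    if not specimens:
        raise ValueError(f"{path}: no specimens found")
    ks = {s.shape[0] for s in specimens}
    if len(ks) > 1:
        raise ValueError(f"{path}: inconsistent landmark counts {sorted(ks)}")
    return LandmarkSet(coords=np.stack(specimens), specimen_ids=ids)


def read_semilandmark_curves(path, landmark_names: list[str]) -> list[list[int]]:
    """Read sliding-curve declarations from YAML: {curve_name: [landmark names]}."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    index = {name: i for i, name in enumerate(landmark_names)}
    curves = []
    for cname, names in spec.items():
        try:
            curves.append([index[n] for n in names])
        except KeyError as exc:
            raise ValueError(f"curve {cname!r}: unknown landmark {exc.args[0]!r}") from exc
    return curves


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(run_config: RunConfig) -> dict:
    """Run smoothing -> (optional) group-mean removal -> canalization estimates.

    Writes the univariate profile (and, when requested, the PLS summary) to
    the output directory together with ``manifest.json`` recording settings,
    seed, package versions and input checksums — enough to reproduce the
    run exactly.  Returns a result bundle dict.
    """
    from . import __version__
    from .model import CanalizationModel, MultivariateCanalization

    cfg = run_config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        data = read_longitudinal_csv(cfg.input_path)

        stage = "error-replicates"
        error_model = None
        if cfg.error_replicates:
            from .univariate import estimate_measurement_error

            reps = read_replicate_csv(cfg.error_replicates)
            if "trait" in reps.columns and cfg.trait is not None:
                reps = reps[reps["trait"] == cfg.trait]
            error_model = estimate_measurement_error(reps)

        stage = "univariate"
        model = CanalizationModel(
            data,
            grid_ages=cfg.grid_ages,
            window=cfg.window,
            trait=cfg.trait,
            group_column=cfg.group_column,
            error_model=error_model,
        )
        results = model.fit()
        profile_path = out / "profile.csv"
        results.profile.to_csv(profile_path)

        bundle: dict = {"profile": results.profile, "results": results}

        stage = "multivariate"
        if cfg.multivariate:
            if cfg.age_a is None or cfg.age_b is None:
                raise ValueError("multivariate run requires age_a and age_b")
            mv = MultivariateCanalization.from_long_frame(
                data,
                age_a=cfg.age_a,
                age_b=cfg.age_b,
                grid_ages=cfg.grid_ages,
                window=cfg.window,
                group_column=cfg.group_column,
            )
            mv_res = mv.fit(k=cfg.pls_k)
            mv_res.to_csv(out)
            bundle["pls"] = mv_res

        stage = "manifest"
        manifest = {
            "settings": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in vars(cfg).items()
            },
            "seed": cfg.seed,
            "versions": {
                "chreodkit": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "inputs": {
                Path(cfg.input_path).name: _sha256(cfg.input_path),
                **(
                    {Path(cfg.error_replicates).name: _sha256(cfg.error_replicates)}
                    if cfg.error_replicates
                    else {}
                ),
            },
            "outputs": [profile_path.name],
            "stages": {
                "group_mean_removal": cfg.group_column is not None,
                "multivariate": cfg.multivariate,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        bundle["manifest"] = manifest
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
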