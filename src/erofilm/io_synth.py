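"""CSV I/O, configuration helpers and synthetic-data generation.

The package's tabular dialect is plain comma-separated CSV with dot
decimals, a header row, and unit-annotated comment lines (``# key = value``)
above it.  :class:`ReleaseCurve` is the in-memory form: a time column plus
named series with units.

The synthetic-data generator runs the forward models at stated "truth"
parameters and applies multiplicative Gaussian noise,
``y_noisy = y (1 + sigma * N(0,1))``, with ``sigma = 0.10`` by default (the
replicate-to-replicate scatter observed on flow-through outlet
concentrations).  All randomness flows through one seeded generator and the
truth parameters plus seed are written to a JSON manifest, so a dataset is
reproducible byte-for-byte.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReleaseCurve",
    "SyntheticSpec",
    "read_release_csv",
    "write_release_csv",
    "mt_from_cs",
    "synthesize",
    "generate_synthetic",
    "load_params_yaml",
]

_FLOAT_FMT = "%.12g"


@dataclass
class ReleaseCurve:
    """A time series bundle: strictly increasing times plus named columns.

    ``data`` maps column name -> array; ``units`` maps column name (or
    ``t``) -> unit string; ``meta`` carries free-form provenance (model,
    truth parameters, seed, flow rate ...).
    """

    t: np.ndarray
    data: dict
    units: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise ValueError("time column must be a non-empty 1D array")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time column must be strictly increasing")
        for k, v in list(self.data.items()):
            v = np.asarray(v, dtype=float)
            if v.shape != self.t.shape:
                raise ValueError(f"column {k!r} length does not match time column")
            self.data[k] = v

    def column(self, name: str) -> np.ndarray:
        return self.data[name]


def mt_from_cs(t, cs, Q) -> np.ndarray:
    """Cumulative release from an outlet concentration series:
    Mt = int Q cs dt (trapezoid)."""
    t = np.asarray(t, float)
    cs = np.asarray(cs, float)
    return np.concatenate([[0.0], np.cumsum(0.5 * Q * (cs[1:] + cs[:-1]) * np.diff(t))])


def write_release_csv(path, curve: ReleaseCurve) -> Path:
    """Write a curve with unit/meta comment lines; deterministic bytes."""
    path = Path(path)
    lines = []
    for k, v in sorted(curve.meta.items()):
        lines.append(f"# meta {k} = {v}")
    for k, v in sorted(curve.units.items()):
        lines.append(f"# unit {k} = {v}")
    df = pd.DataFrame({"t": curve.t, **curve.data})
    body = df.to_csv(index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    return path


def read_release_csv(path) -> ReleaseCurve:
    """Read a curve written by :func:`write_release_csv`.

    Raises a parse error naming the offending line for empty files, missing
    time columns and non-monotone time.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty input file")
    units, meta = {}, {}
    lines = text.splitlines()
    n_comment = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_comment += 1
        body = line[1:].strip()
        try:
            kind, rest = body.split(" ", 1)
            key, value = (s.strip() for s in rest.split("=", 1))
        except ValueError:
            continue
        if kind == "unit":
            units[key] = value
        elif kind == "meta":
            meta[key] = value
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("\n".join(lines[n_comment:])))
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse CSV body: {exc}") from exc
    if "t" not in df.columns:
        raise ValueError(f"{path}: line {n_comment + 1}: missing required column 't'")
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"{path}: line {n_comment + 2 + int(bad[0]) + 1}: time not strictly increasing"
        )
    data = {c: df[c].to_numpy(float) for c in df.columns if c != "t"}
    return ReleaseCurve(t=t, data=data, units=units, meta=meta)


def load_params_yaml(path) -> dict:
    """Load a YAML parameter file into a plain dict."""
    import yaml

    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return out


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a synthetic dataset.

    ``model``: one of ``swelling | franz | usp2 | mftd``; ``truth``: forward
    model parameters (see :func:`synthesize` for the keys each model reads);
    ``times``: sampling instants (s); ``sigma``: multiplicative noise
    fraction; ``replicates``; ``seed``.
    """

    model: str
    truth: dict
    times: np.ndarray
    sigma: float = 0.10
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("swelling", "franz", "usp2", "mftd"):
            raise ValueError(f"unknown generator model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.times = np.asarray(self.times, dtype=float)


def _forward_swelling(truth, times):
    from .swelling import SwellingParams, solve_swelling

    p = SwellingParams.from_config(truth)
    tg = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = solve_swelling(p, t_grid=tg)
    w = np.interp(times, traj.t, traj.weight_ratio)
    return ReleaseCurve(times, {"weight_ratio": w},
                        units={"t": "s", "weight_ratio": "-"},
                        meta={"model": "swelling"})


def _forward_franz(truth, times):
    from .franz import DiffusivitySet, FranzGeometry, WithdrawalSchedule, solve_model_III

    geom = FranzGeometry(**truth.get("geometry", {}))
    diff = DiffusivitySet(Dd=truth["Dd"], Dm=truth["Dm"], D0=truth["D0"])
    sched = WithdrawalSchedule(times=times)
    run = solve_model_III(geom, diff, sched, truth.get("donor_mode", "solution"),
                          M0=truth["M0"], **truth.get("solver_kwargs", {}))
    return ReleaseCurve(times, {"cp": run.cp},
                        units={"t": "s", "cp": "kg/m^3"},
                        meta={"model": "franz", "M0": truth["M0"]})


def _forward_usp2(truth, times):
    from .swelling import SwellingParams
    from .usp2 import USP2Config, solve_usp2_release

    p = SwellingParams.from_config(truth["swelling"])
    cfg = USP2Config(swelling=p, DG=truth["DG"], c0=truth["c0"],
                     A=truth.get("A", 1e-4))
    tg = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    rel = solve_usp2_release(cfg, tg, **truth.get("solver_kwargs", {}))
    Mt = np.interp(times, rel.t, rel.Mt)
    return ReleaseCurve(times, {"Mt": Mt, "Mt_frac": Mt / (cfg.A * cfg.c0 * p.L0)},
                        units={"t": "s", "Mt": "kg", "Mt_frac": "-"},
                        meta={"model": "usp2"})


def _forward_mftd(truth, times):
    from .mftd import ChannelGeometry, solve_mftd_release
    from .swelling import SwellingParams

    p = SwellingParams.from_config(truth["swelling"])
    geom = ChannelGeometry(**truth.get("geometry", {}))
    rel = solve_mftd_release(p, geom, truth["DG"], truth["D0"], truth["c0"],
                             t_end=float(times[-1]) * 1.02,
                             **truth.get("solver_kwargs", {}))
    cs = np.interp(times, rel.t, rel.cs)
    Mt = np.interp(times, rel.t, rel.Mt)
    return ReleaseCurve(times, {"cs": cs, "Mt": Mt},
                        units={"t": "s", "cs": "kg/m^3", "Mt": "kg"},
                        meta={"model": "mftd", "Q_m3_s": geom.Q})


_FORWARD = {"swelling": _forward_swelling, "franz": _forward_franz,
            "usp2": _forward_usp2, "mftd": _forward_mftd}


def synthesize(spec: SyntheticSpec):
    """Run the named forward model and apply noise.

    Returns ``(clean, replicates, manifest)``: the noise-free curve, a list
    of noisy replicate curves, and a manifest dict recording truth and seed.
    """
    clean = _FORWARD[spec.model](spec.truth, spec.times)
    rng = np.random.default_rng(spec.seed)
    reps = []
    for r in range(spec.replicates):
        data = {}
        for k, v in clean.data.items():
            noise = 1.0 + spec.sigma * rng.standard_normal(len(v))
            data[k] = np.maximum(v * noise, 0.0)
        meta = dict(clean.meta, replicate=r, sigma=spec.sigma, seed=spec.seed)
        reps.append(ReleaseCurve(clean.t.copy(), data, dict(clean.units), meta))
    manifest = {
        "model": spec.model,
        "truth": _jsonable(spec.truth),
        "sigma": spec.sigma,
        "replicates": spec.replicates,
        "seed": spec.seed,
        "n_times": int(len(spec.times)),
    }
    return clean, reps, manifest


def generate_synthetic(spec: SyntheticSpec, outdir) -> list:
    """Write the dataset (CSV replicates + truth manifest) to ``outdir``.

    Re-running with the same spec reproduces identical bytes.  Returns the
    list of paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clean, reps, manifest = synthesize(spec)
    paths = []
    p = outdir / f"{spec.model}_clean.csv"
    write_release_csv(p, clean)
    paths.append(p)
    for r, curve in enumerate(reps):
        p = outdir / f"{spec.model}_rep{r}.csv"
        write_release_csv(p, curve)
        paths.append(p)
    mpath = outdir / f"{spec.model}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths.append(mpath)
    return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
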