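"""Run configuration, config-file parsing, and result serialization.

Configs are flat YAML key/value documents.  Any :class:`ModelParams` field
may be given either a scalar or a list; list-valued keys define a sweep
grid.  Convenience aliases ``N``, ``s``, ``p``, ``e`` expand to the
symmetric parameterization (equal demes, ``s1 = s = -s2``, all plasticity
effects ``p``, reciprocal migration).  Unknown keys are rejected by name.

Outputs are tab-separated tables with a commented header block carrying the
fully resolved configuration, the master seed, and the software version, so
every result file is self-describing and reruns are byte-identical.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import ModelParams

_PARAM_FIELDS = set(ModelParams.__dataclass_fields__)
_ALIASES = {"N", "s", "p", "e"}
_CONTROL_FIELDS = {
    "experiment", "replicates", "out", "record_every", "seed",
    "first_mutant_locus", "burn_in", "pre_window", "post_window", "preset",
}
_EXPERIMENTS = ("replicate", "ensemble", "sweep", "switch", "equilibrium")

#: Parameter presets mirroring commonly used survey configurations: a
#: selection grid under continuous migration with full plasticity effect
#: and free recombination.
PRESETS: dict[str, dict] = {
    "fig1a": {
        "s1": [0.0, 0.005, 0.01, 0.015, 0.02, 0.025, 0.03],
        "p": 1.0,
        "r": 0.5,
        "I": 1,
        "experiment": "sweep",
    },
}

_DEFAULTS = {"I": 1, "r": 0.5, "sigma": 0.0, "intro_prob": 0.001, "max_gens_factor": 100}

_RANGES = {
    "N1": "positive integer", "N2": "positive integer",
    "s1": "(-1, 1)", "s2": "(-1, 1)",
    "p_a1": "[0, 1]", "p_d1": "[0, 1]", "p_a2": "[0, 1]", "p_d2": "[0, 1]",
    "e1": "integer in [0, N1]", "e2": "integer in [0, N2]",
    "I": "positive integer", "r": "[0, 0.5]", "sigma": ">= 0",
    "intro_prob": "[0, 1]", "max_gens_factor": "positive integer",
}


@dataclass
class RunConfig:
    """Resolved configuration for one run: model parameters, the experiment
    selector, optional sweep grid, and run-control settings."""

    params: ModelParams
    experiment: str = "ensemble"
    grid: dict = field(default_factory=dict)
    replicates: int = 1000
    out: str | None = None
    record_every: int = 0
    seed: int = 0
    first_mutant_locus: str = "random"
    burn_in: int | None = None
    pre_window: int = 200
    post_window: int = 800

    def resolved(self) -> dict:
        """Flat key/value view (round-trips through parse_config)."""
        d = {k: getattr(self.params, k) for k in sorted(_PARAM_FIELDS) if k != "seed"}
        for k, v in sorted(self.grid.items()):
            d[k] = list(v)
        d.update(
            experiment=self.experiment,
            replicates=self.replicates,
            record_every=self.record_every,
            seed=self.seed,
            first_mutant_locus=self.first_mutant_locus,
            pre_window=self.pre_window,
            post_window=self.post_window,
        )
        if self.burn_in is not None:
            d["burn_in"] = self.burn_in
        if self.out is not None:
            d["out"] = self.out
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=True))


def _expand_aliases(raw: dict) -> dict:
    out = dict(raw)
    if "N" in out:
        v = out.pop("N")
        out.setdefault("N1", v)
        out.setdefault("N2", v)
    if "s" in out:
        v = out.pop("s")
        out.setdefault("s1", v)
        if not isinstance(v, list):
            out.setdefault("s2", -v)
    if "p" in out:
        v = out.pop("p")
        for k in ("p_a1", "p_d1", "p_a2", "p_d2"):
            out.setdefault(k, v)
    if "e" in out:
        v = out.pop("e")
        out.setdefault("e1", v)
        if not isinstance(v, list):
            out.setdefault("e2", v)
    return out


def parse_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file and/or keyword overrides.

    Overrides take precedence over the file; ``None``-valued overrides are
    ignored.  Unknown keys and out-of-range values are rejected with a
    message naming the offending key.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a flat key/value mapping")
        raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})

    if "preset" in raw:
        name = raw.pop("preset")
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        merged = dict(PRESETS[name])
        merged.update(raw)
        raw = merged

    raw = _expand_aliases(raw)
    unknown = set(raw) - _PARAM_FIELDS - _CONTROL_FIELDS
    if unknown:
        k = sorted(unknown)[0]
        raise ValueError(
            f"unknown configuration key {k!r}; valid keys are ModelParams fields "
            f"{sorted(_PARAM_FIELDS)} (or aliases {sorted(_ALIASES)}) and "
            f"{sorted(_CONTROL_FIELDS)}"
        )

    grid = {k: list(v) for k, v in raw.items() if k in _PARAM_FIELDS and isinstance(v, list)}
    scalars = {k: v for k, v in raw.items() if k in _PARAM_FIELDS and not isinstance(v, list)}
    for k, v in _DEFAULTS.items():
        scalars.setdefault(k, v)
    # grid keys need a placeholder scalar so the base ModelParams validates
    for k, values in grid.items():
        if not values:
            raise ValueError(f"grid key {k!r} has an empty list of values")
        scalars.setdefault(k, values[0])
    seed = int(raw.get("seed", 0))
    scalars["seed"] = seed
    try:
        params = ModelParams(**scalars)
    except TypeError as exc:
        raise ValueError(f"incomplete configuration: {exc}") from exc
    except ValueError as exc:
        msg = str(exc)
        key = msg.split()[0]
        rng_hint = _RANGES.get(key)
        raise ValueError(f"{msg}" + (f" (valid range: {rng_hint})" if rng_hint else "")) from exc

    experiment = raw.get("experiment", "ensemble")
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; choose from {_EXPERIMENTS}")
    return RunConfig(
        params=params,
        experiment=experiment,
        grid=grid,
        replicates=int(raw.get("replicates", 1000)),
        out=raw.get("out"),
        record_every=int(raw.get("record_every", 0)),
        seed=seed,
        first_mutant_locus=raw.get("first_mutant_locus", "random"),
        burn_in=raw.get("burn_in"),
        pre_window=int(raw.get("pre_window", 200)),
        post_window=int(raw.get("post_window", 800)),
    )


def write_results(table: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Write a result table as TSV with a commented header block carrying
    the resolved configuration, master seed, and software version.  Output
    bytes are deterministic for fixed inputs."""
    buf = io.StringIO()
    buf.write(f"# plastimod {__version__}\n")
    if config is not None:
        for k, v in sorted(config.resolved().items()):
            buf.write(f"# {k} = {v}\n")
    table.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results` (header comments are
    skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_header(path) -> dict[str, str]:
    """Recover the key/value header block of a result file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                out[k.strip()] = v.strip()
    return out
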