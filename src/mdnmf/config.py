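"""Flat key-value run configuration and manifests.

A run config is a plain text file of ``key = value`` lines (``#`` comments
allowed); every key has a documented default and unknown keys are rejected.
A fully resolved config can be written back as a manifest next to the run
outputs, and re-parsing the manifest reproduces the identical config.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict

from .exceptions import ParameterError

__all__ = ["RunConfig", "parse_config", "write_manifest"]


@dataclass
class RunConfig:
    """All tunables of the pipeline, flat, with defaults."""

    rank: int | None = None          # latent dimension; None -> min(m, d, 20)
    lambda_m: float = 0.01           # microbe graph penalty weight
    lambda_d: float = 0.01           # disease graph penalty weight
    lambda_l: float = 0.1            # L2,1 row-sparsity weight
    n_neighbors: int = 5             # K of the KNN graphs
    gamma_m_prime: float = 1.0       # raw GIP bandwidth, microbe side
    gamma_d_prime: float = 1.0       # raw GIP bandwidth, disease side
    init: str = "nndsvd"             # nndsvd | abs_svd
    inertia: str = "nesterov"        # nesterov | none | float constant
    max_iter: int = 500
    tol: float = 1e-6
    eps_row: float = 1e-2            # Huber knee of the smoothed L2,1 term
    data_step_only: bool = False  # drop the graph/L2,1 curvature safeguard
    n_folds: int = 5
    n_repeats: int = 100
    seed: int = 0

    def model_kwargs(self) -> dict:
        """Keyword arguments for :class:`~mdnmf.model.MicrobeDiseaseNMF`."""
        d = asdict(self)
        for key in ("n_folds", "n_repeats"):
            d.pop(key)
        inertia = d["inertia"]
        try:
            d["inertia"] = float(inertia)
        except (TypeError, ValueError):
            pass
        return d


def _coerce(key: str, value: str, target_type):
    value = value.strip()
    if target_type is bool or key == "data_step_only":
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ParameterError(f"config key {key}: expected a boolean, got {value!r}")
    if key == "rank":
        return None if value.lower() in ("none", "") else int(value)
    if key in ("n_neighbors", "max_iter", "n_folds", "n_repeats", "seed"):
        return int(value)
    if key in ("init", "inertia"):
        return value
    return float(value)


def parse_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Parse a flat key=value config file; ``overrides`` (e.g. CLI flags)
    take precedence over file values.  Unknown keys raise, listing the valid
    ones."""
    valid = {f.name: f.type for f in fields(RunConfig)}
    values: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            for no, ln in enumerate(fh, start=1):
                ln = ln.split("#", 1)[0].strip()
                if not ln:
                    continue
                if "=" not in ln:
                    raise ParameterError(f"{path}: line {no}: expected key = value")
                key, value = (part.strip() for part in ln.split("=", 1))
                if key not in valid:
                    raise ParameterError(
                        f"{path}: line {no}: unknown key {key!r}; "
                        f"valid keys: {', '.join(sorted(valid))}"
                    )
                values[key] = _coerce(key, value, valid[key])
    for key, value in (overrides or {}).items():
        if key not in valid:
            raise ParameterError(
                f"unknown config key {key!r}; valid keys: {', '.join(sorted(valid))}"
            )
        if value is not None:
            values[key] = value
    return RunConfig(**values)


def write_manifest(config: RunConfig, path) -> None:
    """Write the fully resolved config as a re-parseable manifest."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key} = {'none' if value is None else value}\n")
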