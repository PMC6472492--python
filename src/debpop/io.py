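"""Run configuration and tabular output plumbing shared by the CLI.

A run config is a YAML (or JSON) mapping with optional blocks

    model:    ModelParams fields (defaults reproduce the packaged
              defaults.yaml)
    numerics: NumericsConfig fields
    ebt:      EBTOptions fields
    seed:     global random seed (used only by the synthetic-data
              generator and bootstrap CIs)
    output_dir, log_level

Unknown keys anywhere are rejected with a message listing every
offender.  ``load_config`` on an empty file yields the full default
parameterization.  The fully resolved config can be echoed next to the
outputs for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .ebt import EBTOptions
from .params import ModelParams, NumericsConfig

__all__ = ["RunConfig", "load_config", "dump_config", "write_table"]

log = logging.getLogger("debpop")


@dataclass
class RunConfig:
    """Fully resolved configuration of one CLI run."""

    model: ModelParams = field(default_factory=ModelParams)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    ebt: EBTOptions = field(default_factory=EBTOptions)
    seed: int = 0
    output_dir: Path = Path(".")
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model.to_dict(),
            "numerics": dataclasses.asdict(self.numerics),
            "ebt": dataclasses.asdict(self.ebt),
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
        }


def _build(cls, block: Mapping[str, Any], name: str, errors: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(block) - known)
    if unknown:
        errors.append(
            f"{name}: unknown key(s) {', '.join(unknown)}; "
            f"valid keys are {', '.join(sorted(known))}"
        )
        block = {k: v for k, v in block.items() if k in known}
    try:
        if cls is ModelParams:
            return ModelParams.from_dict(block)
        return cls(**block)
    except (ValueError, TypeError) as err:
        errors.append(f"{name}: {err}")
        return cls()


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON run config; None means all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")

    errors: list[str] = []
    top_known = {"model", "numerics", "ebt", "seed", "output_dir", "log_level"}
    model_fields = {f.name for f in dataclasses.fields(ModelParams)}
    # flat model parameters at top level are accepted for convenience
    flat_model = {k: v for k, v in data.items() if k in model_fields}
    unknown = sorted(set(data) - top_known - model_fields)
    if unknown:
        errors.append(
            f"top level: unknown key(s) {', '.join(unknown)}; valid keys are "
            f"{', '.join(sorted(top_known))} or flat model parameter names"
        )

    model_block = dict(data.get("model", {}))
    model_block.update(flat_model)
    cfg = RunConfig(
        model=_build(ModelParams, model_block, "model", errors),
        numerics=_build(NumericsConfig, dict(data.get("numerics", {})), "numerics", errors),
        ebt=_build(EBTOptions, dict(data.get("ebt", {})), "ebt", errors),
        seed=int(data.get("seed", 0)),
        output_dir=Path(data.get("output_dir", ".")),
        log_level=str(data.get("log_level", "INFO")),
    )
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the fully resolved config (reproducibility record)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def write_table(
    rows: Sequence[Mapping[str, Any]] | pd.DataFrame,
    path: str | Path,
    schema: Sequence[str] | None = None,
) -> None:
    """Write rows as CSV with a deterministic column order.

    Floats are written with full repr precision (value round-trips
    through re-reading).  Empty input produces a header-only file;
    an existing file is overwritten.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if schema is not None:
        if df.empty and len(df.columns) == 0:
            df = pd.DataFrame(columns=list(schema))
        else:
            missing = set(schema) - set(df.columns)
            if missing:
                raise ValueError(f"rows missing schema column(s): {sorted(missing)}")
            df = df[list(schema)]
    df.to_csv(path, index=False)
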