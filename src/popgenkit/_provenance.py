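"""Output provenance: seeded stage RNGs and self-describing TSV headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing of the stage name, so adding
    a stage never perturbs another stage's randomness."""
    digest = hashlib.sha256(stage.encode()).digest()
    return int.from_bytes(digest[:4], "little") ^ (int(global_seed) & 0xFFFFFFFF)


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(global_seed, stage))


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    tool: str,
    seed: int | None = None,
    params: dict | None = None,
) -> None:
    """Write a TSV with a provenance header comment (tool, version, seed,
    resolved parameters).  Deterministic: no timestamps."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "tool": tool,
        "version": __version__,
        "seed": seed,
        "params": params or {},
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
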