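"""Deterministic seed derivation, fixtures, and file output.

All randomness in a run flows from a single master seed through named
substreams, derived by hashing (master seed, purpose tag, replicate
index).  The derivation is stable across platforms and runs, so any
record is reproducible from the configuration file and master seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vessels import VesselPattern, generate_random, generate_regular

__all__ = [
    "derive_seed",
    "substream",
    "make_fixture",
    "RunManifest",
    "write_outputs",
    "write_grid",
    "read_grid",
]


def derive_seed(master_seed: int, tag: str, index: int = 0) -> int:
    """Stable sub-seed below 2³¹ from (master seed, purpose tag, index)."""
    digest = hashlib.sha256(f"{master_seed}:{tag}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(master_seed: int, tag: str, index: int = 0) -> np.random.Generator:
    """Named random substream derived from the master seed."""
    return np.random.default_rng(derive_seed(master_seed, tag, index))


def make_fixture(kind: str, N: int, v: int = 0,
                 rng: np.random.Generator | None = None,
                 spacing: int | None = None, separation: float = 1.0,
                 patch_origin: tuple[int, int] = (0, 0),
                 patch_size: int = 3) -> VesselPattern:
    """Deterministic vessel-pattern fixtures for tests and examples.

    ``kind``:
      * ``"csr"`` — ``v`` uniform-random lattice sites (needs ``rng``);
      * ``"regular"`` — regular grid at the given ``spacing``;
      * ``"clustered"`` — ``v`` distinct sites inside one small patch;
      * ``"two-point"`` — exactly two points separated by ``separation``
        along the x axis, for estimator hand-checks.
    """
    if kind == "csr":
        if rng is None:
            raise ValueError("csr fixture needs an rng")
        return generate_random(N, v, rng)
    if kind == "regular":
        if spacing is None:
            raise ValueError("regular fixture needs a spacing")
        return generate_regular(N, spacing)
    if kind == "clustered":
        if rng is None:
            raise ValueError("clustered fixture needs an rng")
        ox, oy = patch_origin
        sites = [(ox + i, oy + j) for i in range(patch_size)
                 for j in range(patch_size)]
        if v > len(sites):
            raise ValueError("patch too small for requested vessel count")
        chosen = rng.choice(len(sites), size=v, replace=False)
        return VesselPattern(N=N, coords=np.array([sites[i] for i in chosen]))
    if kind == "two-point":
        x0 = N // 2 - int(round(separation)) // 2
        coords = np.array([[x0, N // 2], [x0 + int(round(separation)), N // 2]])
        return VesselPattern(N=N, coords=coords)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Snapshot of a run: resolved configuration, seeds, and outputs."""

    config: dict
    master_seed: int
    derived_seeds: dict = field(default_factory=dict)
    software_version: str = ""
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def write_grid(grid: np.ndarray, path) -> None:
    """Integer or float lattice snapshot as a delimited-text matrix
    (one row per lattice row)."""
    if np.issubdtype(np.asarray(grid).dtype, np.integer):
        np.savetxt(path, grid, fmt="%d", delimiter="\t")
    else:
        np.savetxt(path, grid, fmt="%.8g", delimiter="\t")


def read_grid(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def write_outputs(records: list[dict] | pd.DataFrame, manifest: RunManifest,
                  out_dir, force: bool = False,
                  records_name: str = "records.csv") -> dict:
    """Write per-record CSV plus the manifest JSON; refuse to overwrite
    existing outputs unless ``force``.  Returns the file inventory
    (filename -> checksum), which is also stored in the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inventory = {}
    if records is not None and len(records):
        df = pd.DataFrame(records)
        target = out_dir / records_name
        if target.exists():
            if not force:
                raise FileExistsError(f"{target} exists (use force=True)")
            existing = pd.read_csv(target, nrows=0)
            if list(existing.columns) != list(df.columns):
                raise ValueError(
                    f"column mismatch writing {target}: "
                    f"{list(existing.columns)} != {list(df.columns)}")
        df.to_csv(target, index=False)
        inventory[records_name] = _checksum(target)
    manifest.outputs.update(inventory)
    mpath = out_dir / "manifest.json"
    if mpath.exists() and not force:
        raise FileExistsError(f"{mpath} exists (use force=True)")
    mpath.write_text(manifest.to_json())
    return inventory
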