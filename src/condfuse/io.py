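"""Readers and writers for the tool's text formats, plus run configs.

Formats (all plain text, 1-based ids in files):

* **topology** — header with box length, then a bead table
  ``bead_id chain_id bead_index flavor x y z`` and a bond table
  ``sticker_i sticker_j``.
* **XYZ** — standard xyz frames; the element column carries the flavor
  (``S`` spacer, ``A``/``B`` stickers).
* **LAMMPS-style dump** — ``ITEM: TIMESTEP / NUMBER OF ATOMS /
  BOX BOUNDS pp pp pp / ATOMS id mol type x y z`` with type 1 = spacer,
  2 = flavor A, 3 = flavor B.
* **bonds TSV** — per-frame sticker pair list; **event TSV** — the bond
  event log; **hills TSV** — deposited metadynamics Gaussians.
* **run config** — YAML, schema-validated, energies in "kT" or
  "kcal/mol" via an explicit ``unit`` key.

Coordinates are written with 6 decimals; topology and bond identity
round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import kt_to_kcal
from .metadynamics import HillStore, WellTemperedParams
from .model_core import ForceField, ThermoParams
from .state import SystemState

_FLAVOR_TO_SYMBOL = {0: "S", 1: "A", 2: "B"}
_SYMBOL_TO_FLAVOR = {v: k for k, v in _FLAVOR_TO_SYMBOL.items()}


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        super().__init__(f"line {line}: {message}" if line else message)
        self.line = line


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# topology


def write_topology(path, state: SystemState) -> None:
    lines = [
        "# condfuse topology (units: angstrom; 1-based ids)",
        f"box_length {state.box_length:.6f}",
        f"n_beads {state.n_beads}",
        "# bead_id chain_id bead_index flavor x y z",
        "BEADS",
    ]
    for k in range(state.n_beads):
        x, y, z = state.positions[k]
        lines.append(
            f"{k + 1} {state.chain_id[k] + 1} {state.bead_index[k] + 1} "
            f"{_FLAVOR_TO_SYMBOL[int(state.flavor[k])]} "
            f"{x:.6f} {y:.6f} {z:.6f}")
    lines.append("BONDS")
    for i, j in state.bonded_pairs():
        lines.append(f"{i + 1} {j + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path) -> SystemState:
    box = None
    beads, bonds = [], []
    section = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEADS":
            section = "beads"
            continue
        if line == "BONDS":
            section = "bonds"
            continue
        parts = line.split()
        if section is None:
            if parts[0] == "box_length":
                box = float(parts[1])
            elif parts[0] == "n_beads":
                pass
            else:
                raise ParseError(f"unexpected header field {parts[0]!r}", lineno)
        elif section == "beads":
            if len(parts) != 7:
                raise ParseError("bead record needs 7 fields", lineno)
            beads.append(parts)
        else:
            if len(parts) != 2:
                raise ParseError("bond record needs 2 fields", lineno)
            bonds.append((int(parts[0]) - 1, int(parts[1]) - 1))
    if box is None:
        raise ParseError("missing box_length header")
    n = len(beads)
    positions = np.array([[float(b[4]), float(b[5]), float(b[6])] for b in beads])
    state = SystemState(
        positions=positions,
        velocities=np.zeros((n, 3)),
        box_length=box,
        chain_id=np.array([int(b[1]) - 1 for b in beads]),
        bead_index=np.array([int(b[2]) - 1 for b in beads]),
        flavor=np.array([_SYMBOL_TO_FLAVOR[b[3]] for b in beads], dtype=np.int8),
    )
    for i, j in bonds:
        state.bond_partner[i], state.bond_partner[j] = j, i
    return state


# ---------------------------------------------------------------------------
# XYZ


def write_xyz(path, state: SystemState, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(f"step={state.step} box={state.box_length:.6f}\n")
        for k in range(state.n_beads):
            x, y, z = state.positions[k]
            fh.write(f"{_FLAVOR_TO_SYMBOL[int(state.flavor[k])]} "
                     f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path):
    """Yield (comment, symbols, positions) for each frame in an XYZ file."""
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise ParseError("expected atom count", k + 1)
        comment = lines[k + 1]
        symbols, positions = [], []
        for row in lines[k + 2:k + 2 + n]:
            parts = row.split()
            symbols.append(parts[0])
            positions.append([float(v) for v in parts[1:4]])
        yield comment, symbols, np.array(positions)
        k += 2 + n


# ---------------------------------------------------------------------------
# LAMMPS-style dump


def write_dump(path, state: SystemState, append: bool = False) -> None:
    mode = "a" if append else "w"
    box = state.box_length
    with open(path, mode) as fh:
        fh.write("ITEM: TIMESTEP\n")
        fh.write(f"{state.step}\n")
        fh.write("ITEM: NUMBER OF ATOMS\n")
        fh.write(f"{state.n_beads}\n")
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for _ in range(3):
            fh.write(f"0.000000 {box:.6f}\n")
        fh.write("ITEM: ATOMS id mol type x y z\n")
        for k in range(state.n_beads):
            x, y, z = state.positions[k]
            fh.write(f"{k + 1} {state.chain_id[k] + 1} "
                     f"{int(state.flavor[k]) + 1} "
                     f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_dump_frames(path):
    """Yield (step, box_length, chain_id, flavor, positions) per frame."""
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].startswith("ITEM: TIMESTEP"):
            raise ParseError("expected ITEM: TIMESTEP", k + 1)
        step = int(lines[k + 1])
        if not lines[k + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError("expected ITEM: NUMBER OF ATOMS", k + 3)
        n = int(lines[k + 3])
        if not lines[k + 4].startswith("ITEM: BOX BOUNDS"):
            raise ParseError("expected ITEM: BOX BOUNDS", k + 5)
        lo, hi = (float(v) for v in lines[k + 5].split()[:2])
        box = hi - lo
        if not lines[k + 8].startswith("ITEM: ATOMS"):
            raise ParseError("expected ITEM: ATOMS", k + 9)
        rows = np.array([lines[k + 9 + m].split() for m in range(n)])
        order = np.argsort(rows[:, 0].astype(int))
        rows = rows[order]
        yield (step, box,
               rows[:, 1].astype(int) - 1,
               (rows[:, 2].astype(int) - 1).astype(np.int8),
               rows[:, 3:6].astype(float))
        k += 9 + n


# ---------------------------------------------------------------------------
# bond pair lists / event logs / hills


def write_bonds(path, state: SystemState, append: bool = False) -> None:
    mode = "a" if append else "w"
    pairs = state.bonded_pairs()
    with open(path, mode) as fh:
        fh.write(f"# step {state.step} n_bonds {len(pairs)}\n")
        for i, j in pairs:
            fh.write(f"{i + 1}\t{j + 1}\n")


def read_bonds(path):
    """Yield (step, pairs) per frame of a bonds TSV (0-based pairs)."""
    step, pairs = None, []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            if step is not None:
                yield step, np.array(pairs, dtype=np.int64).reshape(-1, 2)
            step = int(raw.split()[2])
            pairs = []
        elif raw.strip():
            i, j = raw.split()
            pairs.append((int(i) - 1, int(j) - 1))
    if step is not None:
        yield step, np.array(pairs, dtype=np.int64).reshape(-1, 2)


def write_events(path, log) -> None:
    log.to_dataframe().to_csv(path, sep="\t", index=False)


def write_hills(path, store: HillStore) -> None:
    with open(path, "w") as fh:
        fh.write("step\tcenter\twidth\theight\n")
        for s, c, w, h in zip(store.steps, store.centers, store.widths,
                              store.heights):
            fh.write(f"{s}\t{c:.6f}\t{w:.6f}\t{h:.8f}\n")


def read_hills(path) -> HillStore:
    store = HillStore()
    lines = Path(path).read_text().splitlines()
    for raw in lines[1:]:
        s, c, w, h = raw.split("\t")
        store.append(float(c), float(w), float(h), int(s))
    return store


# ---------------------------------------------------------------------------
# full-precision restart (runtime output; text dumps are for analysis)


def save_restart(path, state: SystemState) -> None:
    """Full-precision state snapshot so resumed runs are bit-identical."""
    np.savez(path,
             positions=state.positions, velocities=state.velocities,
             box_length=state.box_length, step=state.step,
             chain_id=state.chain_id, bead_index=state.bead_index,
             flavor=state.flavor, bond_partner=state.bond_partner,
             bond_formed_step=state.bond_formed_step)


def load_restart(path) -> SystemState:
    data = np.load(path)
    return SystemState(
        positions=data["positions"], velocities=data["velocities"],
        box_length=float(data["box_length"]), step=int(data["step"]),
        chain_id=data["chain_id"], bead_index=data["bead_index"],
        flavor=data["flavor"], bond_partner=data["bond_partner"],
        bond_formed_step=data["bond_formed_step"])


# ---------------------------------------------------------------------------
# run configuration


_FF_KEYS = {"Kb", "R0_backbone", "kappa", "sigma", "Rmax_LJ", "Es", "Ens",
            "R0_bond", "Rcut_bond", "p_on", "p_off", "bond_update_interval",
            "lj_shift", "unit"}
_THERMO_KEYS = {"T", "damp", "dt", "mass"}
_META_KEYS = {"w0", "sigma_G", "pace", "gamma"}
_SYSTEM_KEYS = {"box_length", "n_chains_per_flavor", "n_beads",
                "sticker_indices", "conformation", "min_separation"}
_TOP_KEYS = {"protocol", "seed", "steps", "system", "force_field", "thermo",
             "metadynamics", "snapshot_every", "metrics_every", "out"}
_PROTOCOLS = {"collapse", "relax", "fuse", "phase-scan"}


@dataclass
class RunConfig:
    protocol: str
    seed: int
    steps: int
    system: dict
    force_field: ForceField
    thermo: ThermoParams
    metadynamics: WellTemperedParams
    snapshot_every: int = 1000
    metrics_every: int = 500
    out: str = "run_out"
    raw: dict = field(default_factory=dict, repr=False)


def _check_keys(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {name}: {sorted(unknown)}")


def parse_config(data: dict) -> RunConfig:
    _check_keys(data, _TOP_KEYS, "config")
    protocol = data.get("protocol", "relax")
    if protocol not in _PROTOCOLS:
        raise ConfigError(f"protocol must be one of {sorted(_PROTOCOLS)}")

    ff_block = dict(data.get("force_field", {}))
    _check_keys(ff_block, _FF_KEYS, "force_field")
    unit = ff_block.pop("unit", "kcal/mol")
    if unit not in ("kT", "kcal/mol"):
        raise ConfigError("force_field.unit must be 'kT' or 'kcal/mol'")
    thermo_block = dict(data.get("thermo", {}))
    _check_keys(thermo_block, _THERMO_KEYS, "thermo")
    thermo = ThermoParams(**thermo_block)
    if unit == "kT":  # convert the two well depths once at load time
        for key in ("Es", "Ens"):
            if key in ff_block:
                ff_block[key] = kt_to_kcal(ff_block[key], thermo.T)
    ff = ForceField(**ff_block)

    meta_block = dict(data.get("metadynamics", {}))
    _check_keys(meta_block, _META_KEYS, "metadynamics")
    meta = WellTemperedParams(T=thermo.T, **meta_block)

    system = dict(data.get("system", {}))
    _check_keys(system, _SYSTEM_KEYS, "system")

    return RunConfig(
        protocol=protocol,
        seed=int(data.get("seed", 0)),
        steps=int(data.get("steps", 10000)),
        system=system,
        force_field=ff,
        thermo=thermo,
        metadynamics=meta,
        snapshot_every=int(data.get("snapshot_every", 1000)),
        metrics_every=int(data.get("metrics_every", 500)),
        out=str(data.get("out", "run_out")),
        raw=data,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return parse_config(data)


def provenance_record(config: RunConfig, extra: dict | None = None) -> dict:
    """Machine-readable record sufficient to re-execute a run."""
    from . import __version__

    blob = json.dumps(config.raw, sort_keys=True, default=str).encode()
    record = {
        "version": __version__,
        "seed": config.seed,
        "protocol": config.protocol,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "force_field": asdict(config.force_field),
        "thermo": asdict(config.thermo),
        "metadynamics": asdict(config.metadynamics),
        "conventions": {
            "bending_angle": "deflection between successive bond vectors; "
                             "straight chain has theta=0",
            "lj_truncation": "shifted" if config.force_field.lj_shift
                             else "plain (unshifted)",
            "chain_center": "bead n//2 (1-based), the 17th bead of a 35-mer",
            "cluster_separation": "3 Rg (all beads, center of geometry), +x axis",
            "sigma_cluster": "2 Rg of the relaxed cluster",
            "entropy_log_base": "natural",
        },
    }
    if extra:
        record.update(extra)
    return record
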