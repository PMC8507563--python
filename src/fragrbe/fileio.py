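"""File dialects for normalized spectra (SPC) and depth-dose (DDD) tables.

Two self-describing, versioned dialects are provided:

* a **text dialect** — UTF-8, tab-separated, ``#`` comment headers, values
  written with 12 significant digits; the natural choice for fixtures and
  inspection;
* a **binary dialect** — HDF5 with one group per species, round-tripping
  bit-exactly.

Both record the energy unit (MeV/u), the grids, and a provenance block
(seed, configuration hash, tool version).  The format is selected from
the file suffix: ``.h5``/``.hdf5`` is binary, anything else is text.

Reading an SPC file re-validates the normalization contract: the
primary-proton particle numbers in the first depth slice must sum to one.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from . import __version__ as _version
from .errors import FormatError, ValidationError
from .field import DepthDoseSet, SPCTable
from .grids import DepthGrid, EnergyGrid
from .particles import ANY_GENERATION, ParticleType

SPC_MAGIC = "fragrbe-spc"
DDD_MAGIC = "fragrbe-ddd"
DIALECT_VERSION = 1
_FMT = "%.12e"
#: Reading tolerance on the first-slice primary normalization.
NORM_TOL = 1e-9


def _is_binary(path) -> bool:
    return Path(path).suffix.lower() in (".h5", ".hdf5")


def _species_key(t: ParticleType) -> str:
    return f"A{t.A}_Z{t.Z}_G{t.generation}"


def _parse_species_key(key: str) -> ParticleType:
    try:
        a, z, g = (int(part[1:]) for part in key.split("_"))
        return ParticleType(a, z, g)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"malformed species key {key!r}") from exc


def _provenance(meta: dict) -> dict:
    return {
        "seed": meta.get("seed"),
        "config_hash": meta.get("config_hash"),
        "tool_version": _version,
    }


def _check_spc_normalized(table: SPCTable) -> None:
    norm = table.primary_normalization()
    if abs(norm - 1.0) > NORM_TOL:
        raise ValidationError(
            "SPC content violates the normalization contract: primary-proton "
            f"numbers at zero depth sum to {norm!r}, not 1 (the spectra must "
            "be normalized to unit primary content in the first slice)")


# ---------------------------------------------------------------------------
# SPC
# ---------------------------------------------------------------------------

def write_spc(path, table: SPCTable) -> None:
    """Write an SPC table; dialect chosen from the file suffix."""
    _check_spc_normalized(table)
    if _is_binary(path):
        _write_spc_h5(path, table)
    else:
        _write_spc_text(path, table)


def read_spc(path) -> SPCTable:
    """Read an SPC table; validates dialect version and normalization."""
    table = _read_spc_h5(path) if _is_binary(path) else _read_spc_text(path)
    _check_spc_normalized(table)
    return table


def _write_spc_text(path, table: SPCTable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SPC_MAGIC} v{DIALECT_VERSION}\n")
        fh.write("# energy_unit MeV/u\n")
        fh.write(f"# eprim {_FMT % table.eprim}\n")
        g = table.depth_grid
        fh.write(f"# depth_grid {g.n_slices} {_FMT % g.length}\n")
        for k, v in _provenance(table.metadata).items():
            fh.write(f"# provenance.{k} {v}\n")
        fh.write(f"# n_species {len(table.n)}\n")
        fh.write("# columns species slice bin N dN/dE\n")
        dnde = table.dnde
        for t in table.species:
            eg = table.energy_grids[t]
            fh.write(f"# species {_species_key(t)} n_bins {eg.n_bins} "
                     f"upper {_FMT % eg.upper}\n")
            arr = table.n[t]
            dd = dnde[t]
            iz, ie = np.nonzero(arr)
            for i, j in zip(iz, ie):
                fh.write(f"{_species_key(t)}\t{i}\t{j}\t"
                         f"{_FMT % arr[i, j]}\t{_FMT % dd[i, j]}\n")


def _read_spc_text(path) -> SPCTable:
    header: dict[str, str] = {}
    species_specs: dict[str, tuple[int, float]] = {}
    rows: list[tuple[str, int, int, float]] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != f"# {SPC_MAGIC} v{DIALECT_VERSION}":
            raise FormatError(
                f"not a {SPC_MAGIC} v{DIALECT_VERSION} file: {first!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                if parts[0] == "species":
                    species_specs[parts[1]] = (int(parts[3]), float(parts[5]))
                else:
                    header[parts[0]] = " ".join(parts[1:])
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"malformed SPC data row: {line!r}")
            rows.append((cols[0], int(cols[1]), int(cols[2]), float(cols[3])))
    try:
        eprim = float(header["eprim"])
        n_slices, length = header["depth_grid"].split()
        grid = DepthGrid(int(n_slices), float(length))
    except KeyError as exc:
        raise FormatError(f"missing SPC header field: {exc}") from exc
    egrids = {_parse_species_key(k): EnergyGrid(nb, up)
              for k, (nb, up) in species_specs.items()}
    n = {t: np.zeros((grid.n_slices, eg.n_bins)) for t, eg in egrids.items()}
    keymap = {k: _parse_species_key(k) for k in species_specs}
    for key, i, j, val in rows:
        try:
            n[keymap[key]][i, j] = val
        except (KeyError, IndexError) as exc:
            raise FormatError(f"SPC row outside declared grids: {key} "
                              f"slice={i} bin={j}") from exc
    meta = {k[len("provenance."):]: v for k, v in header.items()
            if k.startswith("provenance.")}
    return SPCTable(eprim, grid, egrids, n, meta)


def _write_spc_h5(path, table: SPCTable) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["magic"] = SPC_MAGIC
        f.attrs["version"] = DIALECT_VERSION
        f.attrs["energy_unit"] = "MeV/u"
        f.attrs["eprim"] = table.eprim
        f.attrs["n_slices"] = table.depth_grid.n_slices
        f.attrs["depth_length"] = table.depth_grid.length
        for k, v in _provenance(table.metadata).items():
            f.attrs[f"provenance.{k}"] = str(v)
        dnde = table.dnde
        for t in table.species:
            grp = f.create_group(_species_key(t))
            eg = table.energy_grids[t]
            grp.attrs["n_bins"] = eg.n_bins
            grp.attrs["upper"] = eg.upper
            grp.create_dataset("edges", data=eg.edges)
            grp.create_dataset("N", data=table.n[t])
            grp.create_dataset("dNdE", data=dnde[t])


def _read_spc_h5(path) -> SPCTable:
    with h5py.File(path, "r") as f:
        if f.attrs.get("magic") != SPC_MAGIC:
            raise FormatError(f"{path} is not a {SPC_MAGIC} container")
        if int(f.attrs.get("version", -1)) != DIALECT_VERSION:
            raise FormatError(
                f"unsupported {SPC_MAGIC} version {f.attrs.get('version')}")
        grid = DepthGrid(int(f.attrs["n_slices"]), float(f.attrs["depth_length"]))
        egrids, n = {}, {}
        for key, grp in f.items():
            t = _parse_species_key(key)
            egrids[t] = EnergyGrid(int(grp.attrs["n_bins"]),
                                   float(grp.attrs["upper"]))
            n[t] = np.asarray(grp["N"])
        meta = {k[len("provenance."):]: f.attrs[k] for k in f.attrs
                if k.startswith("provenance.")}
        return SPCTable(float(f.attrs["eprim"]), grid, egrids, n, meta)


# ---------------------------------------------------------------------------
# DDD
# ---------------------------------------------------------------------------

def write_ddd(path, dose_set: DepthDoseSet) -> None:
    """Write a depth-dose set; dialect chosen from the file suffix."""
    if _is_binary(path):
        _write_ddd_h5(path, dose_set)
    else:
        _write_ddd_text(path, dose_set)


def read_ddd(path) -> DepthDoseSet:
    return _read_ddd_h5(path) if _is_binary(path) else _read_ddd_text(path)


def _write_ddd_text(path, ds: DepthDoseSet) -> None:
    species = ds.species
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {DDD_MAGIC} v{DIALECT_VERSION}\n")
        fh.write("# energy_unit MeV/u\n")
        fh.write(f"# eprim {_FMT % ds.eprim}\n")
        g = ds.depth_grid
        fh.write(f"# depth_grid {g.n_slices} {_FMT % g.length}\n")
        for k, v in _provenance(ds.metadata).items():
            fh.write(f"# provenance.{k} {v}\n")
        fh.write("# columns depth_cm "
                 + " ".join(_species_key(t) for t in species) + " total\n")
        total = ds.total
        centers = g.centers
        for i in range(g.n_slices):
            row = [_FMT % centers[i]]
            row += [_FMT % ds.dose[t][i] for t in species]
            row.append(_FMT % total[i])
            fh.write("\t".join(row) + "\n")


def _read_ddd_text(path) -> DepthDoseSet:
    header: dict[str, str] = {}
    data: list[list[float]] = []
    columns: list[str] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != f"# {DDD_MAGIC} v{DIALECT_VERSION}":
            raise FormatError(
                f"not a {DDD_MAGIC} v{DIALECT_VERSION} file: {first!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "columns":
                    columns = parts[2:-1]  # species keys between depth, total
                elif parts:
                    header[parts[0]] = " ".join(parts[1:])
                continue
            data.append([float(x) for x in line.split("\t")])
    try:
        eprim = float(header["eprim"])
        n_slices, length = header["depth_grid"].split()
        grid = DepthGrid(int(n_slices), float(length))
    except KeyError as exc:
        raise FormatError(f"missing DDD header field: {exc}") from exc
    arr = np.asarray(data)
    if arr.shape != (grid.n_slices, len(columns) + 2):
        raise FormatError("DDD data block does not match declared grids")
    dose = {_parse_species_key(c): arr[:, 1 + j].copy()
            for j, c in enumerate(columns)}
    meta = {k[len("provenance."):]: v for k, v in header.items()
            if k.startswith("provenance.")}
    return DepthDoseSet(eprim, grid, dose, meta)


def _write_ddd_h5(path, ds: DepthDoseSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["magic"] = DDD_MAGIC
        f.attrs["version"] = DIALECT_VERSION
        f.attrs["energy_unit"] = "MeV/u"
        f.attrs["eprim"] = ds.eprim
        f.attrs["n_slices"] = ds.depth_grid.n_slices
        f.attrs["depth_length"] = ds.depth_grid.length
        for k, v in _provenance(ds.metadata).items():
            f.attrs[f"provenance.{k}"] = str(v)
        for t in ds.species:
            f.create_dataset(_species_key(t), data=ds.dose[t])
        f.create_dataset("total", data=ds.total)


def _read_ddd_h5(path) -> DepthDoseSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("magic") != DDD_MAGIC:
            raise FormatError(f"{path} is not a {DDD_MAGIC} container")
        if int(f.attrs.get("version", -1)) != DIALECT_VERSION:
            raise FormatError(
                f"unsupported {DDD_MAGIC} version {f.attrs.get('version')}")
        grid = DepthGrid(int(f.attrs["n_slices"]), float(f.attrs["depth_length"]))
        dose = {_parse_species_key(k): np.asarray(v)
                for k, v in f.items() if k != "total"}
        meta = {k[len("provenance."):]: f.attrs[k] for k in f.attrs
                if k.startswith("provenance.")}
        return DepthDoseSet(float(f.attrs["eprim"]), grid, dose, meta)


# ---------------------------------------------------------------------------
# LQ tables
# ---------------------------------------------------------------------------

def write_lq_table(path, lq) -> None:
    """Text dialect for ion LQ tables: rows (A, Z, gen, E, alpha, beta)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fragrbe-lq v{DIALECT_VERSION}\n")
        fh.write(f"# tissue alpha_x {_FMT % lq.tissue.alpha_x} beta_x "
                 f"{_FMT % lq.tissue.beta_x} dt {_FMT % lq.tissue.dt}\n")
        fh.write(f"# provenance {lq.provenance}\n")
        fh.write("# columns A Z gen E_mev_u alpha_gy beta_gy2\n")
        for t in sorted(lq.alpha):
            centers = lq.energy_grids[t].centers
            for e, al, be in zip(centers, lq.alpha[t], lq.beta[t]):
                fh.write(f"{t.A}\t{t.Z}\t{t.generation}\t{_FMT % e}\t"
                         f"{_FMT % al}\t{_FMT % be}\n")


def read_lq_table(path, tissue):
    """Read an external LQ table (bypasses the built-in parametrization).

    Energies must form a uniform grid per species, matching the writer's
    layout.
    """
    from .radiobiology import LQTable

    per_species: dict[ParticleType, list[tuple[float, float, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != f"# fragrbe-lq v{DIALECT_VERSION}":
            raise FormatError(f"not a fragrbe LQ table: {first!r}")
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, z, g, e, al, be = line.split("\t")
            t = ParticleType(int(a), int(z), int(g))
            per_species.setdefault(t, []).append(
                (float(e), float(al), float(be)))
    egrids, alpha, beta = {}, {}, {}
    for t, rows in per_species.items():
        rows.sort()
        e = np.array([r[0] for r in rows])
        width = e[1] - e[0] if len(e) > 1 else 2 * e[0]
        egrids[t] = EnergyGrid(len(e), float(e[-1] + width / 2))
        alpha[t] = np.array([r[1] for r in rows])
        beta[t] = np.array([r[2] for r in rows])
    return LQTable(tissue, egrids, alpha, beta, provenance=f"file:{path}")
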