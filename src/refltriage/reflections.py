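"""Reflection containers, mmCIF/CSV I/O, merging, binning, completeness.

The in-memory container is a :class:`ReflectionSet`: a pandas DataFrame of
observations plus the unit cell and space group.  Columns ``h, k, l, I,
sigI`` are mandatory; ``Iplus/sigIplus/Iminus/sigIminus`` (Bijvoet-split
intensities) and ``F`` (amplitude) are optional.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd

from .symmetry import SpaceGroupOps, UnitCell, classify_reflections, parse_spacegroup

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectionSet",
    "ShellScheme",
    "MergeStats",
    "read_reflections",
    "write_reflections",
    "merge_equivalents",
    "bin_by_resolution",
    "completeness",
    "i_over_sigma",
    "assign_free_set",
]

OPTIONAL_COLUMNS = ("Iplus", "sigIplus", "Iminus", "sigIminus", "F")
CSV_COLUMNS = ("h", "k", "l", "I", "sigI") + OPTIONAL_COLUMNS

# packed integer encoding for fast lexicographic comparisons; |index| < 512
_SHIFT = 512


def _encode(hkl: np.ndarray) -> np.ndarray:
    h = hkl.astype(np.int64)
    return ((h[..., 0] + _SHIFT) << 20) | ((h[..., 1] + _SHIFT) << 10) | (h[..., 2] + _SHIFT)


def _decode(code: np.ndarray) -> np.ndarray:
    out = np.empty(code.shape + (3,), dtype=np.int64)
    out[..., 0] = (code >> 20) - _SHIFT
    out[..., 1] = ((code >> 10) & 0x3FF) - _SHIFT
    out[..., 2] = (code & 0x3FF) - _SHIFT
    return out


def asu_map(hkl: np.ndarray, sg: SpaceGroupOps, friedel: bool = True) -> np.ndarray:
    """Canonical ASU representative for each index row.

    Among all symmetry equivalents (plus Friedel mates when ``friedel``)
    the lexicographically greatest (h, k, l) is chosen — a group-agnostic
    total order.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    rots = sg.rotation_stack()
    mapped = np.einsum("nj,mjk->mnk", hkl, rots)
    if friedel:
        mapped = np.concatenate([mapped, -mapped], axis=0)
    codes = _encode(mapped)
    return _decode(codes.max(axis=0))


@dataclass
class ReflectionSet:
    """Reflection observations plus crystal metadata."""

    cell: UnitCell
    sg: SpaceGroupOps
    data: pd.DataFrame
    merged: bool = False
    anomalous: bool = False
    n_rejected: int = 0

    def __post_init__(self):
        for col in ("h", "k", "l", "I", "sigI"):
            if col not in self.data.columns:
                raise ValueError(f"missing required column {col!r}")
        self.data = self.data.reset_index(drop=True)
        if "d" not in self.data.columns:
            self.data["d"] = self.cell.d_values(self.hkl)

    @property
    def hkl(self) -> np.ndarray:
        return self.data[["h", "k", "l"]].to_numpy(dtype=np.int64)

    @property
    def d(self) -> np.ndarray:
        return self.data["d"].to_numpy()

    @property
    def d_min(self) -> float:
        return float(self.data["d"].min())

    @property
    def d_max(self) -> float:
        return float(self.data["d"].max())

    def __len__(self) -> int:
        return len(self.data)

    def classify(self):
        """(epsilon, centric, absent) arrays, cached on the frame."""
        if "epsilon" not in self.data.columns:
            eps, centric, absent = classify_reflections(self.hkl, self.sg)
            self.data["epsilon"] = eps
            self.data["centric"] = centric
            self.data["absent"] = absent
        return (
            self.data["epsilon"].to_numpy(),
            self.data["centric"].to_numpy(bool),
            self.data["absent"].to_numpy(bool),
        )

    def asu_indices(self, friedel: Optional[bool] = None) -> np.ndarray:
        if friedel is None:
            friedel = not self.anomalous
        return asu_map(self.hkl, self.sg, friedel=friedel)

    def intensity_lookup(self) -> dict[tuple[int, int, int], int]:
        """Map canonical ASU index -> row position (merged sets)."""
        keys = asu_map(self.hkl, self.sg, friedel=not self.anomalous)
        return {tuple(k): i for i, k in enumerate(keys)}

    def with_data(self, data: pd.DataFrame, **kw) -> "ReflectionSet":
        out = replace(self, data=data.reset_index(drop=True))
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class ShellScheme:
    """Resolution shells: boundaries is a strictly decreasing d list of
    length n_shells + 1 spanning [d_min, d_max]."""

    boundaries: np.ndarray

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if not np.all(np.diff(self.boundaries) < 0):
            raise ValueError("shell boundaries must be strictly decreasing")

    @property
    def n_shells(self) -> int:
        return len(self.boundaries) - 1

    def assign(self, d: np.ndarray) -> np.ndarray:
        """Shell index per reflection (0 = lowest resolution)."""
        s3 = 1.0 / np.asarray(d) ** 3
        edges = 1.0 / self.boundaries**3  # increasing
        idx = np.searchsorted(edges[1:-1], s3, side="left")
        return np.clip(idx, 0, self.n_shells - 1)

    def centers_d(self) -> np.ndarray:
        mid = 0.5 * (1.0 / self.boundaries[:-1] ** 3 + 1.0 / self.boundaries[1:] ** 3)
        return mid ** (-1.0 / 3.0)


@dataclass
class MergeStats:
    r_merge: float
    r_meas: float
    multiplicity: float
    n_unique: int
    n_obs: int


# ---------------------------------------------------------------------------
# I/O


def _sg_from_string(name: str) -> SpaceGroupOps:
    try:
        return parse_spacegroup(name)
    except ValueError:
        # fall back to gemmi's tables for symbols outside the short list
        gsg = gemmi.find_spacegroup_by_name(name)
        if gsg is None:
            raise ValueError(f"unsupported space group: {name!r}")
        return parse_spacegroup([op.triplet() for op in gsg.operations()])


def read_reflections(
    path,
    format: str = "auto",
    cell: Optional[UnitCell] = None,
    sg: Optional[SpaceGroupOps] = None,
) -> ReflectionSet:
    """Read a reflection file (structure-factor mmCIF or the CSV dialect)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif", ".ent") else "csv"
    if format == "mmcif":
        return _read_mmcif(path, cell, sg)
    if format == "csv":
        return _read_csv(path, cell, sg)
    raise ValueError(f"unknown format {format!r}")


def _finalize(df, cell, sg, merged, anomalous):
    if cell is None or sg is None:
        raise ValueError("symmetry required: unit cell and space group not found")
    zero = (df[["h", "k", "l"]] == 0).all(axis=1)
    n_rejected = int(zero.sum())
    if n_rejected:
        logger.warning("rejected %d record(s) with hkl = (0,0,0)", n_rejected)
        df = df[~zero]
    if not len(df):
        raise ValueError("no data columns: file holds no usable reflections")
    return ReflectionSet(
        cell=cell, sg=sg, data=df.reset_index(drop=True),
        merged=merged, anomalous=anomalous, n_rejected=n_rejected,
    )


def _read_csv(path, cell, sg) -> ReflectionSet:
    merged = False
    anomalous_hint = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("cell:"):
                vals = [float(x) for x in body.split(":", 1)[1].split()]
                cell = cell or UnitCell(*vals)
            elif body.startswith("spacegroup:"):
                sg = sg or _sg_from_string(body.split(":", 1)[1].strip())
            elif body.startswith("merged:"):
                merged = body.split(":", 1)[1].strip().lower() == "true"
            elif body.startswith("anomalous:"):
                anomalous_hint = body.split(":", 1)[1].strip().lower() == "true"
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("h", "k", "l") if c not in df.columns]
    if missing:
        raise ValueError(f"no data columns: missing {missing}")
    if "I" not in df.columns:
        if "F" in df.columns:
            df["I"] = df["F"] ** 2
            df["sigI"] = 1.0
        else:
            raise ValueError("no data columns: need I or F")
    df = df[[c for c in CSV_COLUMNS if c in df.columns]]
    anomalous = (
        anomalous_hint
        if anomalous_hint is not None
        else ("Iplus" in df.columns or "Iminus" in df.columns)
    )
    return _finalize(df, cell, sg, merged, anomalous)


_CIF_ITEMS = {
    "h": "index_h",
    "k": "index_k",
    "l": "index_l",
    "I": "intensity_meas",
    "sigI": "intensity_sigma",
    "Iplus": "pdbx_I_plus",
    "sigIplus": "pdbx_I_plus_sigma",
    "Iminus": "pdbx_I_minus",
    "sigIminus": "pdbx_I_minus_sigma",
    "F": "F_meas_au",
}


def _read_mmcif(path, cell, sg) -> ReflectionSet:
    doc = gemmi.cif.read(str(path))
    block = None
    for b in doc:
        if b.find_loop("_refln.index_h"):
            block = b
            break
    if block is None:
        raise ValueError("no data columns: no _refln loop found")
    if cell is None:
        vals = [block.find_value(f"_cell.{i}") for i in
                ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta", "angle_gamma")]
        if all(v is not None for v in vals):
            cell = UnitCell(*(float(gemmi.cif.as_number(v)) for v in vals))
    if sg is None:
        for item in ("_symmetry.space_group_name_H-M", "_space_group.name_H-M_alt"):
            v = block.find_value(item)
            if v is not None:
                sg = _sg_from_string(gemmi.cif.as_string(v))
                break
    cols = {}
    for key, item in _CIF_ITEMS.items():
        loop = block.find_loop(f"_refln.{item}")
        if loop:
            vals = [gemmi.cif.as_number(v) if v not in ("?", ".") else np.nan for v in loop]
            cols[key] = np.asarray(vals)
    for key in ("h", "k", "l"):
        if key not in cols:
            raise ValueError("no data columns: incomplete _refln indices")
        cols[key] = cols[key].astype(int)
    if "I" not in cols:
        if "F" in cols:
            cols["I"] = cols["F"] ** 2
            cols["sigI"] = np.ones_like(cols["I"])
        else:
            raise ValueError("no data columns: no intensity or amplitude item")
    if "sigI" not in cols:
        cols["sigI"] = np.ones_like(cols["I"])
    df = pd.DataFrame(cols)
    mrg = block.find_value("_refltriage.merged")
    merged = mrg is not None and gemmi.cif.as_string(mrg).lower() in ("yes", "true", "1")
    anomalous = "Iplus" in cols or "Iminus" in cols
    return _finalize(df, cell, sg, merged, anomalous)


def write_reflections(rset: ReflectionSet, path, format: str = "auto") -> Path:
    """Write a reflection set; round-trips indices exactly and values to
    6 significant figures."""
    if not len(rset):
        raise ValueError("refusing to write an empty reflection set")
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "csv"
    cols = [c for c in CSV_COLUMNS if c in rset.data.columns]
    df = rset.data[cols]
    if format == "csv":
        with open(path, "w") as fh:
            a, b, c, al, be, ga = rset.cell.parameters()
            fh.write(f"# cell: {a:g} {b:g} {c:g} {al:g} {be:g} {ga:g}\n")
            fh.write(f"# spacegroup: {rset.sg.symbol}\n")
            fh.write(f"# merged: {str(rset.merged).lower()}\n")
            fh.write(f"# anomalous: {str(rset.anomalous).lower()}\n")
            df.to_csv(fh, index=False, float_format="%.6g")
        return path
    if format == "mmcif":
        doc = gemmi.cif.Document()
        block = doc.add_new_block("refltriage")
        a, b, c, al, be, ga = rset.cell.parameters()
        for item, val in (
            ("_cell.length_a", a), ("_cell.length_b", b), ("_cell.length_c", c),
            ("_cell.angle_alpha", al), ("_cell.angle_beta", be), ("_cell.angle_gamma", ga),
        ):
            block.set_pair(item, f"{val:g}")
        block.set_pair("_symmetry.space_group_name_H-M", gemmi.cif.quote(rset.sg.symbol))
        block.set_pair("_refltriage.merged", "yes" if rset.merged else "no")
        loop = block.init_loop("_refln.", [_CIF_ITEMS[c] for c in cols])
        for row in df.itertuples(index=False):
            out = []
            for colname, v in zip(cols, row):
                if colname in ("h", "k", "l"):
                    out.append(str(int(v)))
                else:
                    out.append("?" if pd.isna(v) else f"{v:.6g}")
            loop.add_row(out)
        doc.write_file(str(path))
        return path
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Merging


def merge_equivalents(rset: ReflectionSet) -> tuple[ReflectionSet, MergeStats]:
    """Merge symmetry-equivalent observations by inverse-variance weighting.

    Friedel mates are collapsed unless the set is anomalous, in which case
    the merged record keeps Bijvoet-separated columns alongside the
    Friedel-averaged intensity.
    """
    if rset.merged:
        raise ValueError("already merged")
    df = rset.data
    sig = df["sigI"].to_numpy()
    if np.any(~(sig > 0)):
        raise ValueError("merging requires sigI > 0 for every observation")
    keys = _encode(asu_map(rset.hkl, rset.sg, friedel=True))
    I = df["I"].to_numpy(float)
    w = 1.0 / sig**2

    order = np.argsort(keys, kind="stable")
    keys_s, I_s, w_s = keys[order], I[order], w[order]
    uniq, start = np.unique(keys_s, return_index=True)
    counts = np.diff(np.append(start, len(keys_s)))
    sw = np.add.reduceat(w_s, start)
    swi = np.add.reduceat(w_s * I_s, start)
    mean_I = swi / sw
    sig_m = 1.0 / np.sqrt(sw)

    # merging residuals over multiply-observed uniques
    mean_per_obs = np.repeat(mean_I, counts)
    n_per_obs = np.repeat(counts, counts)
    dev = np.abs(I_s - mean_per_obs)
    multi = n_per_obs > 1
    denom = np.abs(I_s[multi]).sum()
    r_merge = float(dev[multi].sum() / denom) if denom > 0 else 0.0
    corr = np.sqrt(n_per_obs[multi] / (n_per_obs[multi] - 1.0))
    r_meas = float((corr * dev[multi]).sum() / denom) if denom > 0 else 0.0

    out = pd.DataFrame(_decode(uniq), columns=["h", "k", "l"])
    out["I"] = mean_I
    out["sigI"] = sig_m

    if rset.anomalous:
        # Bijvoet split: sign of each observation relative to the
        # Friedel-collapsed representative
        rep_nf = _encode(asu_map(rset.hkl, rset.sg, friedel=False))
        key_nf_of_rep = _encode(asu_map(_decode(keys), rset.sg, friedel=False))
        is_plus = rep_nf == key_nf_of_rep
        for label, mask in (("plus", is_plus), ("minus", ~is_plus)):
            km, Im, wm = keys[mask], I[mask], w[mask]
            o = np.argsort(km, kind="stable")
            km, Im, wm = km[o], Im[o], wm[o]
            u2, s2 = np.unique(km, return_index=True)
            swm = np.add.reduceat(wm, s2)
            mim = np.add.reduceat(wm * Im, s2) / swm
            col_I = np.full(len(uniq), np.nan)
            col_s = np.full(len(uniq), np.nan)
            pos = np.searchsorted(uniq, u2)
            col_I[pos] = mim
            col_s[pos] = 1.0 / np.sqrt(swm)
            out[f"I{label}"] = col_I
            out[f"sigI{label}"] = col_s

    stats = MergeStats(
        r_merge=r_merge,
        r_meas=r_meas,
        multiplicity=float(len(df) / len(uniq)),
        n_unique=int(len(uniq)),
        n_obs=int(len(df)),
    )
    merged = ReflectionSet(
        cell=rset.cell, sg=rset.sg, data=out, merged=True, anomalous=rset.anomalous
    )
    return merged, stats


# ---------------------------------------------------------------------------
# Binning, completeness, signal to noise


def bin_by_resolution(rset: ReflectionSet, n_shells: int = 20,
                      min_per_shell: int = 40) -> ShellScheme:
    """Equal reciprocal-volume shells (equal 1/d³ increments); shells with
    fewer than ``min_per_shell`` reflections are coalesced with neighbors."""
    d = rset.d
    if len(d) < n_shells:
        warnings.warn("too few reflections for requested shells; using one shell")
        return ShellScheme(np.array([d.max() * 1.0001, d.min() * 0.9999]))
    s3_lo, s3_hi = 1.0 / d.max() ** 3, 1.0 / d.min() ** 3
    edges = np.linspace(s3_lo, s3_hi, n_shells + 1)
    edges[0] *= 0.9999
    edges[-1] *= 1.0001
    s3 = 1.0 / d**3
    counts, _ = np.histogram(s3, bins=edges)
    # coalesce: sweep low->high merging deficient shells into the next one
    keep = [edges[0]]
    acc = 0
    for i in range(n_shells):
        acc += counts[i]
        last = i == n_shells - 1
        if acc >= min_per_shell and not last:
            keep.append(edges[i + 1])
            acc = 0
        elif last:
            if acc >= min_per_shell or len(keep) == 1:
                keep.append(edges[-1])
            else:
                keep[-1] = edges[-1]
    boundaries = np.array(keep) ** (-1.0 / 3.0)
    return ShellScheme(boundaries)


def theoretical_unique(rset: ReflectionSet) -> np.ndarray:
    """All possible unique (canonical-ASU) indices to d_min, absences
    excluded, Friedel collapsed unless anomalous."""
    cell, sg = rset.cell, rset.sg
    d_min, d_max = rset.d_min, rset.d_max
    limits = [int(np.floor(L / d_min)) + 1 for L in (cell.a, cell.b, cell.c)]
    h = np.arange(-limits[0], limits[0] + 1)
    k = np.arange(-limits[1], limits[1] + 1)
    l = np.arange(-limits[2], limits[2] + 1)
    grid = np.array(np.meshgrid(h, k, l, indexing="ij")).reshape(3, -1).T
    grid = grid[np.any(grid != 0, axis=1)]
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ij,jk,ik->i", grid.astype(float), gstar, grid.astype(float))
    d = 1.0 / np.sqrt(inv_d2)
    sel = (d >= d_min * (1 - 1e-9)) & (d <= d_max * (1 + 1e-9))
    grid = grid[sel]
    uniq = np.unique(_encode(asu_map(grid, sg, friedel=not rset.anomalous)))
    uhkl = _decode(uniq)
    _, _, absent = classify_reflections(uhkl, sg)
    return uhkl[~absent]


def completeness(rset: ReflectionSet, scheme: ShellScheme) -> pd.DataFrame:
    """Observed / theoretically possible unique reflections, per shell and
    overall (row ``overall``).  Systematic absences are excluded from both
    numerator and denominator."""
    if not rset.merged:
        raise ValueError("completeness requires a merged set")
    possible = theoretical_unique(rset)
    d_poss = rset.cell.d_values(possible)
    _, _, absent = classify_reflections(rset.hkl, rset.sg)
    obs = rset.hkl[~absent]
    d_obs = rset.d[~absent]
    # count observed only if inside the theoretical sphere
    poss_codes = np.unique(_encode(asu_map(possible, rset.sg, friedel=not rset.anomalous)))
    obs_codes = _encode(asu_map(obs, rset.sg, friedel=not rset.anomalous))
    inside = np.isin(obs_codes, poss_codes)
    rows = []
    shell_obs = scheme.assign(d_obs[inside])
    shell_poss = scheme.assign(d_poss)
    for i in range(scheme.n_shells):
        n_o = int((shell_obs == i).sum())
        n_p = int((shell_poss == i).sum())
        rows.append(
            dict(shell=i, d_high=scheme.boundaries[i + 1], d_low=scheme.boundaries[i],
                 n_obs=n_o, n_possible=n_p,
                 completeness=(n_o / n_p) if n_p else np.nan)
        )
    n_o, n_p = int(inside.sum()), int(len(possible))
    rows.append(dict(shell=-1, d_high=scheme.boundaries[-1], d_low=scheme.boundaries[0],
                     n_obs=n_o, n_possible=n_p,
                     completeness=(n_o / n_p) if n_p else np.nan))
    return pd.DataFrame(rows)


def i_over_sigma(rset: ReflectionSet, scheme: ShellScheme) -> pd.DataFrame:
    """Arithmetic mean I/σ per shell and overall; empty shells are NaN."""
    ratio = rset.data["I"].to_numpy() / rset.data["sigI"].to_numpy()
    shell = scheme.assign(rset.d)
    rows = []
    for i in range(scheme.n_shells):
        vals = ratio[shell == i]
        rows.append(dict(shell=i, d_high=scheme.boundaries[i + 1],
                         d_low=scheme.boundaries[i], n=len(vals),
                         i_over_sigma=float(vals.mean()) if len(vals) else np.nan))
    rows.append(dict(shell=-1, d_high=scheme.boundaries[-1], d_low=scheme.boundaries[0],
                     n=len(ratio), i_over_sigma=float(ratio.mean())))
    return pd.DataFrame(rows)


def assign_free_set(rset: ReflectionSet, fraction: float = 0.05,
                    max_count: int = 2000, seed: int = 0) -> np.ndarray:
    """Random cross-validation flags (True = free); free count is
    min(round(fraction·n), max_count)."""
    if not rset.merged:
        raise ValueError("free flags are assigned on merged data")
    n = len(rset)
    if n < 100:
        warnings.warn("fewer than 100 reflections; free set will be tiny")
    n_free = min(int(round(fraction * n)), max_count)
    rng = np.random.default_rng(seed)
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_free, replace=False)] = True
    return flags
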