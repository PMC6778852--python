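"""Native Patterson map from merged intensities and off-origin peak search
for translational noncrystallographic symmetry (tNCS).

The Patterson function P(u) = Σ_h I(h) cos(2π h·u) has peaks at
interatomic difference vectors; two copies of a molecule related by a
pure translation t put roughly half the origin weight at u = t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .reflections import ReflectionSet
from .symmetry import UnitCell

__all__ = ["PattersonGrid", "TNCSPeak", "native_patterson", "find_tncs_peaks",
           "direct_summation_patterson"]


@dataclass
class PattersonGrid:
    dims: tuple[int, int, int]
    values: np.ndarray  # origin-normalized: P(0,0,0) = 100
    cell: UnitCell

    def fractional(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.array(index, dtype=float) / np.array(self.dims)


@dataclass
class TNCSPeak:
    frac: tuple[float, float, float]
    height_pct: float
    d_origin: float


def _expand_to_sphere(rset: ReflectionSet):
    """Symmetry- and Friedel-expand unique reflections to the full sphere."""
    hkl = rset.hkl
    I = rset.data["I"].to_numpy(float)
    rots = rset.sg.rotation_stack()
    mapped = np.einsum("nj,mjk->mnk", hkl, rots).reshape(-1, 3)
    I_all = np.tile(I, len(rots))
    mapped = np.concatenate([mapped, -mapped])
    I_all = np.concatenate([I_all, I_all])
    # deduplicate coincident equivalents (centrics, special positions)
    codes = (mapped[:, 0].astype(np.int64) + 512 << 20) \
        | (mapped[:, 1].astype(np.int64) + 512 << 10) \
        | (mapped[:, 2].astype(np.int64) + 512)
    _, idx = np.unique(codes, return_index=True)
    return mapped[idx], I_all[idx]


def native_patterson(rset: ReflectionSet, grid_factor: int = 3) -> PattersonGrid:
    """FFT Patterson of merged intensities, origin normalized to 100.

    Grid spacing is at most d_min/grid_factor along each cell edge, with
    dimensions rounded up to FFT-friendly (5-smooth) sizes.
    """
    if not len(rset):
        raise ValueError("empty reflection set")
    d_min = rset.d_min
    hkl_all, I_all = _expand_to_sphere(rset)
    dims = []
    for axis, length in enumerate((rset.cell.a, rset.cell.b, rset.cell.c)):
        n = max(int(np.ceil(length * grid_factor / d_min)),
                2 * int(np.abs(hkl_all[:, axis]).max()) + 2)
        dims.append(sp_fft.next_fast_len(n, real=True))
    dims = tuple(dims)
    coeff = np.zeros(dims, dtype=complex)
    idx = tuple(hkl_all[:, i] % dims[i] for i in range(3))
    coeff[idx] = I_all
    values = np.real(sp_fft.ifftn(coeff)) * np.prod(dims)
    origin = values[0, 0, 0]
    if origin <= 0:
        raise ValueError("non-physical intensity set: Patterson origin <= 0")
    values *= 100.0 / origin
    return PattersonGrid(dims=dims, values=values, cell=rset.cell)


def direct_summation_patterson(rset: ReflectionSet, dims: tuple[int, int, int]) -> np.ndarray:
    """Brute-force Patterson on the same grid (reference oracle; O(N·M))."""
    hkl_all, I_all = _expand_to_sphere(rset)
    grids = [np.arange(n) / n for n in dims]
    u = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    phases = 2.0 * np.pi * (u @ hkl_all.T)
    values = (np.cos(phases) * I_all).sum(axis=1).reshape(dims)
    return values * (100.0 / values[0, 0, 0])


def _min_image_distance(frac: np.ndarray, cell: UnitCell) -> float:
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                  indexing="ij")).reshape(3, -1).T
    cand = frac[None, :] + shifts
    cart = cand @ cell.orthogonalization_matrix().T
    return float(np.sqrt((cart**2).sum(axis=1)).min())


def find_tncs_peaks(
    grid: PattersonGrid,
    min_distance: float = 10.0,
    threshold_pct: float = 20.0,
) -> list[TNCSPeak]:
    """Off-origin local maxima of the Patterson, candidate tNCS vectors.

    Peaks closer than ``min_distance`` (Å) to the origin (or any of its
    lattice images) are ignored; positions are refined by per-axis
    quadratic interpolation; Friedel mates ±u are collapsed to one entry.
    """
    v = grid.values
    dims = np.array(grid.dims)
    footprint = ndimage.maximum_filter(v, size=3, mode="wrap")
    local_max = (v >= footprint) & (v >= threshold_pct)
    peaks = []
    for index in np.argwhere(local_max):
        frac = index / dims
        dist = _min_image_distance(frac, grid.cell)
        if dist < min_distance:
            continue
        # quadratic sub-grid interpolation along each axis
        offset = np.zeros(3)
        for ax in range(3):
            im = tuple(np.mod(index - np.eye(3, dtype=int)[ax], dims))
            ip = tuple(np.mod(index + np.eye(3, dtype=int)[ax], dims))
            fm, f0, fp = v[im], v[tuple(index)], v[ip]
            denom = fm - 2.0 * f0 + fp
            if denom < 0:
                offset[ax] = 0.5 * (fm - fp) / denom
        refined = np.mod((index + offset) / dims, 1.0)
        peaks.append(TNCSPeak(
            frac=tuple(float(x) for x in refined),
            height_pct=float(v[tuple(index)]),
            d_origin=dist,
        ))
    # collapse Friedel mates ±u
    kept: list[TNCSPeak] = []
    tol = 1.5 / dims.min()
    for p in sorted(peaks, key=lambda q: -q.height_pct):
        mate = np.mod(-np.array(p.frac), 1.0)
        dup = False
        for q in kept:
            delta = np.abs(np.mod(np.array(q.frac) - mate + 0.5, 1.0) - 0.5)
            if np.all(delta < tol):
                dup = True
                break
        if not dup:
            kept.append(p)
    return kept
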