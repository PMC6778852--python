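"""Wilson scaling, E-value normalization, moment screens, anomaly scans,
anisotropy, screw-axis inference and R factors.

Wilson convention: the mean intensity of a shell at resolution d follows
⟨I⟩ ≈ K · Σ_j f_j²(s) · exp(−2B s²) with s² = 1/(4d²), so the Wilson plot
ln(⟨I/ε⟩ / Σf²) against s² is a line of slope −2B and intercept ln K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .formfactors import protein_composition, sum_f_squared
from .reflections import ReflectionSet, ShellScheme, bin_by_resolution
from .symmetry import SpaceGroupOps

__all__ = [
    "WilsonFit", "AnisoFit", "NormalizedSet", "MomentReport", "RFactorResult",
    "wilson_fit", "normalize", "moments", "nz_curves", "ice_ring_scan",
    "aniso_fit", "detect_screw_axes", "r_factors", "reference_moments",
    "ICE_RING_D_SPACINGS",
]

#: strongest hexagonal-ice powder rings at d ≥ 1.9 Å
ICE_RING_D_SPACINGS = (3.90, 3.67, 3.44, 2.67, 2.25, 2.07, 1.95, 1.92)


# ---------------------------------------------------------------------------
# Wilson fit


@dataclass
class WilsonFit:
    K: float
    B_iso: float
    fit_d_max: float
    residual: float
    n_shells_used: int


def _composition_or_default(rset: ReflectionSet, composition):
    if composition:
        return composition
    # crude protein-like default scaled to the cell volume (~10 Å³/atom
    # at typical solvent content)
    n_atoms = max(int(rset.cell.volume / 10.0 / len(rset.sg.distinct_rotations())), 10)
    return protein_composition(n_atoms)


def wilson_fit(
    rset: ReflectionSet,
    composition: Optional[dict[str, float]] = None,
    scheme: Optional[ShellScheme] = None,
    fit_d_max: float = 4.5,
) -> WilsonFit:
    """Straight-line Wilson fit over shells higher resolution than
    ``fit_d_max``; returns scale K and overall isotropic B (Å²)."""
    composition = _composition_or_default(rset, composition)
    scheme = scheme or bin_by_resolution(rset)
    eps, _, absent = rset.classify()
    use = ~absent
    d = rset.d[use]
    ratio = rset.data["I"].to_numpy()[use] / eps[use]
    shell = scheme.assign(d)
    s2_shell, y_shell = [], []
    for i in range(scheme.n_shells):
        m = shell == i
        if m.sum() < 3:
            continue
        mean_ratio = ratio[m].mean()
        if mean_ratio <= 0:
            continue
        s2 = float((1.0 / (4.0 * d[m] ** 2)).mean())
        d_center = 1.0 / (2.0 * np.sqrt(s2))
        if d_center >= fit_d_max:
            continue
        y = np.log(mean_ratio / float(sum_f_squared(composition, np.array([s2]))[0]))
        s2_shell.append(s2)
        y_shell.append(y)
    if len(s2_shell) < 3:
        raise ValueError("resolution too low for Wilson fit (< 3 shells inside range)")
    s2_arr, y_arr = np.array(s2_shell), np.array(y_shell)
    slope, intercept = np.polyfit(s2_arr, y_arr, 1)
    resid = float(np.sqrt(np.mean((y_arr - (slope * s2_arr + intercept)) ** 2)))
    return WilsonFit(K=float(np.exp(intercept)), B_iso=float(-slope / 2.0),
                     fit_d_max=fit_d_max, residual=resid, n_shells_used=len(s2_arr))


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class NormalizedSet:
    """Per-reflection E² (ε-corrected) and Z = I/⟨I⟩ with classification."""

    rset: ReflectionSet
    scheme: ShellScheme
    data: pd.DataFrame  # h,k,l,d,I,epsilon,centric,absent,shell,E2,Z

    def acentric(self, include_absent: bool = False) -> pd.DataFrame:
        m = ~self.data["centric"]
        if not include_absent:
            m &= ~self.data["absent"]
        return self.data[m]

    def centric(self) -> pd.DataFrame:
        return self.data[self.data["centric"] & ~self.data["absent"]]


def normalize(rset: ReflectionSet, scheme: Optional[ShellScheme] = None) -> NormalizedSet:
    """E²(h) = I(h) / (ε · ⟨I/ε⟩_shell);  Z(h) = I(h) / ⟨I⟩_shell.

    Shell means are taken over the working set with systematic absences
    excluded, so ⟨E²⟩ = 1 within each shell by construction.
    """
    if not rset.merged:
        raise ValueError("normalization expects a merged set")
    scheme = scheme or bin_by_resolution(rset)
    eps, centric, absent = rset.classify()
    I = rset.data["I"].to_numpy(float)
    shell = scheme.assign(rset.d)
    E2 = np.full(len(rset), np.nan)
    Z = np.full(len(rset), np.nan)
    for i in range(scheme.n_shells):
        m = shell == i
        work = m & ~absent
        if work.sum() == 0:
            continue
        mean_ie = (I[work] / eps[work]).mean()
        mean_i = I[work].mean()
        if mean_ie > 0:
            E2[m] = I[m] / (eps[m] * mean_ie)
        if mean_i > 0:
            Z[m] = I[m] / mean_i
    df = pd.DataFrame({
        "h": rset.data["h"], "k": rset.data["k"], "l": rset.data["l"],
        "d": rset.d, "I": I, "epsilon": eps, "centric": centric,
        "absent": absent, "shell": shell, "E2": E2, "Z": Z,
    })
    return NormalizedSet(rset=rset, scheme=scheme, data=df)


# ---------------------------------------------------------------------------
# Moments and N(Z)


@dataclass
class MomentReport:
    I2_over_I_sq_acentric: float
    I2_over_I_sq_centric: Optional[float]
    mean_abs_E2m1: float
    F_sq_ratio: float
    n_acentric: int
    expected_untwinned: dict
    expected_perfect_twin: dict
    warning: Optional[str] = None


def reference_moments(twinned: bool, n: int = 400_000, seed: int = 7) -> dict:
    """Monte-Carlo reference moments for ideal acentric intensities.

    Untwinned acentric intensities are exponential; a perfect twin is the
    average of two independent exponentials.
    """
    rng = np.random.default_rng(seed)
    I = rng.exponential(size=n)
    if twinned:
        I = 0.5 * (I + rng.exponential(size=n))
    E2 = I / I.mean()
    F = np.sqrt(I)
    return {
        "I2_over_I_sq": float((I**2).mean() / I.mean() ** 2),
        "mean_abs_E2m1": float(np.abs(E2 - 1.0).mean()),
        "F_sq_ratio": float(F.mean() ** 2 / (F**2).mean()),
    }


def moments(norm: NormalizedSet, oracle_n: int = 400_000, oracle_seed: int = 7) -> MomentReport:
    """Intensity-ratio twinning screen with MC reference values."""
    ac = norm.acentric()
    warning = None
    if len(ac) < 500:
        warning = f"only {len(ac)} acentric reflections; moments are unreliable"
    # moments are taken on shell-normalized intensities (E²) so that the
    # overall resolution falloff does not inflate the ratios
    E2 = ac["E2"].to_numpy()
    F = np.sqrt(np.clip(E2, 0.0, None))
    ce = norm.centric()
    I2c = None
    if len(ce) >= 100:
        e2c = ce["E2"].to_numpy()
        I2c = float((e2c**2).mean() / e2c.mean() ** 2)
    return MomentReport(
        I2_over_I_sq_acentric=float((E2**2).mean() / E2.mean() ** 2),
        I2_over_I_sq_centric=I2c,
        mean_abs_E2m1=float(np.abs(E2 - 1.0).mean()),
        F_sq_ratio=float(F.mean() ** 2 / (F**2).mean()),
        n_acentric=int(len(ac)),
        expected_untwinned=reference_moments(False, oracle_n, oracle_seed),
        expected_perfect_twin=reference_moments(True, oracle_n, oracle_seed),
        warning=warning,
    )


@dataclass
class NZCurves:
    z_grid: np.ndarray
    acentric: Optional[np.ndarray]
    centric: Optional[np.ndarray]
    acentric_ref: np.ndarray
    centric_ref: np.ndarray
    n_acentric: int
    n_centric: int


def nz_curves(norm: NormalizedSet, n_points: int = 50, z_max: float = 4.0) -> NZCurves:
    """Cumulative distributions N(Z) of normalized intensities.

    References: acentric 1 − e^{−Z}; centric erf(√(Z/2)).  Negative Z
    (possible for noisy weak data) counts below every positive grid point.
    """
    grid = np.linspace(z_max / n_points, z_max, n_points)

    def cumulative(z_vals):
        return np.array([(z_vals <= g).mean() for g in grid])

    ac = norm.acentric()["Z"].to_numpy()
    ce = norm.centric()["Z"].to_numpy()
    return NZCurves(
        z_grid=grid,
        acentric=cumulative(ac) if len(ac) >= 500 else None,
        centric=cumulative(ce) if len(ce) >= 500 else None,
        acentric_ref=1.0 - np.exp(-grid),
        centric_ref=special.erf(np.sqrt(grid / 2.0)),
        n_acentric=int(len(ac)),
        n_centric=int(len(ce)),
    )


# ---------------------------------------------------------------------------
# Ice-ring / mean-intensity anomaly scan


@dataclass
class AnomalyScan:
    ice_rings: list       # dicts: d_range, z_score, d_ice
    other_anomalies: list  # dicts: d_range, z_score
    performed: bool
    note: Optional[str] = None


def ice_ring_scan(rset: ReflectionSet, z_threshold: float = 5.0,
                  shell_width: float = 0.005) -> AnomalyScan:
    """Scan thin 1/d² shells of mean normalized intensity for spikes.

    Each thin shell's mean Z is compared against the median of its 10
    neighboring shells, in units of the standard error expected from the
    neighbors' within-shell scatter; z-scores above threshold are flagged,
    as an ice ring when the shell intersects a known hexagonal-ice
    d-spacing and as a generic mean-intensity anomaly otherwise.
    """
    if rset.d_min > 4.0:
        return AnomalyScan([], [], performed=False,
                           note="resolution does not extend beyond 4 Å; scan skipped")
    norm = normalize(rset)
    good = ~norm.data["absent"].to_numpy()
    z_vals = norm.data["Z"].to_numpy()[good]
    inv_d2 = 1.0 / norm.data["d"].to_numpy()[good] ** 2
    lo, hi = inv_d2.min(), inv_d2.max()
    edges = np.arange(lo, hi + shell_width, shell_width)
    if len(edges) < 12:
        return AnomalyScan([], [], performed=False, note="resolution range too narrow")
    idx = np.clip(np.digitize(inv_d2, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    means = np.full(n_bins, np.nan)
    stds = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        m = idx == i
        counts[i] = m.sum()
        if counts[i] >= 5:
            means[i] = z_vals[m].mean()
            stds[i] = z_vals[m].std(ddof=1)
    ice, other = [], []
    for i in range(n_bins):
        if not np.isfinite(means[i]):
            continue
        neigh_idx = [j for j in range(max(0, i - 5), min(n_bins, i + 6))
                     if j != i and np.isfinite(means[j])]
        if len(neigh_idx) < 5:
            continue
        med = np.median(means[neigh_idx])
        # expected scatter of this shell's mean, from the neighbors'
        # within-shell variance (immune to inflation by the spike itself)
        noise = np.nanmean(stds[neigh_idx]) / np.sqrt(counts[i])
        if not noise > 0:
            continue
        z = (means[i] - med) / noise
        if z > z_threshold:
            d_hi, d_lo = edges[i + 1] ** -0.5, edges[i] ** -0.5
            hit = [di for di in ICE_RING_D_SPACINGS if d_hi <= di <= d_lo]
            entry = dict(d_range=(float(d_lo), float(d_hi)), z_score=float(z))
            if hit:
                entry["d_ice"] = hit[0]
                ice.append(entry)
            else:
                other.append(entry)
    return AnomalyScan(ice_rings=ice, other_anomalies=other, performed=True)


# ---------------------------------------------------------------------------
# Anisotropic Wilson fit


@dataclass
class AnisoFit:
    beta: np.ndarray          # symmetric B tensor, Å²
    eigenvalues: np.ndarray   # B1 >= B2 >= B3, Å²
    delta_B: float
    ratio: float
    K: float
    constrained_isotropic: bool = False


_FAMILY_BASES = {
    # symmetric basis matrices for the free tensor components per family,
    # Cartesian frame with the unique/principal axis along z (c)
    "triclinic": [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)],
    "monoclinic": [(0, 0), (1, 1), (2, 2), (0, 2)],  # unique axis b -> y; xz cross term
    "orthorhombic": [(0, 0), (1, 1), (2, 2)],
    "tetragonal": [((0, 0), (1, 1)), (2, 2)],
    "trigonal": [((0, 0), (1, 1)), (2, 2)],
    "hexagonal": [((0, 0), (1, 1)), (2, 2)],
}


def _family_design(family: str):
    spec = _FAMILY_BASES.get(family)
    if spec is None:
        return None  # cubic: isotropic by constraint
    bases = []
    for entry in spec:
        mat = np.zeros((3, 3))
        pairs = entry if isinstance(entry[0], tuple) else (entry,)
        for i, j in pairs:
            mat[i, j] = 1.0
            mat[j, i] = 1.0
        bases.append(mat)
    return bases


def aniso_fit(
    rset: ReflectionSet,
    composition: Optional[dict[str, float]] = None,
    fit_d_max: float = 4.5,
    constrain: Optional[str] = None,
) -> AnisoFit:
    """Symmetry-constrained least-squares anisotropic Wilson fit.

    Model: ln(I(h)/Σf²) = ln K − ½ sᵀ B s with s the reciprocal-space
    vector in Cartesian Å⁻¹, B constrained by the crystal family.  For an
    isotropic B the model reduces to the Wilson line, and the constrained
    isotropic path delegates to :func:`wilson_fit` so the two agree exactly.
    """
    if len(rset) < 1000:
        raise ValueError("anisotropy fit needs at least 1000 reflections")
    composition = _composition_or_default(rset, composition)
    family = rset.sg.crystal_family
    if constrain == "isotropic" or family == "cubic":
        wf = wilson_fit(rset, composition, fit_d_max=fit_d_max)
        beta = np.eye(3) * wf.B_iso
        ev = np.array([wf.B_iso] * 3)
        return AnisoFit(beta=beta, eigenvalues=ev, delta_B=0.0, ratio=0.0,
                        K=wf.K, constrained_isotropic=True)
    bases = _family_design(family)
    eps, _, absent = rset.classify()
    I = rset.data["I"].to_numpy(float)
    use = (~absent) & (I > 0) & (rset.d < fit_d_max)
    if use.sum() < 200:
        raise ValueError("too few reflections inside the anisotropy fit range")
    s = rset.cell.reciprocal_cartesian(rset.hkl[use])
    s2 = (s**2).sum(axis=1)
    y = np.log(I[use] / eps[use]) - np.log(sum_f_squared(composition, s2 / 4.0))
    design = [np.ones(use.sum())]
    for mat in bases:
        design.append(-0.5 * np.einsum("ni,ij,nj->n", s, mat, s))
    A = np.column_stack(design)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    beta = np.zeros((3, 3))
    for cval, mat in zip(coef[1:], bases):
        beta += cval * mat
    ev = np.sort(np.linalg.eigvalsh(beta))[::-1]
    delta = float(ev[0] - ev[-1])
    mean_b = float(ev.mean())
    return AnisoFit(beta=beta, eigenvalues=ev, delta_B=delta,
                    ratio=delta / mean_b if mean_b != 0 else 0.0,
                    K=float(np.exp(coef[0])))


# ---------------------------------------------------------------------------
# Screw-axis inference from axial intensities


#: screw hypotheses compatible with each crystal family:
#: (axis index, label, modulus of the reflection condition)
_SCREW_HYPOTHESES = {
    "triclinic": [],
    "monoclinic": [(1, "21", 2)],
    "orthorhombic": [(0, "21", 2), (1, "21", 2), (2, "21", 2)],
    "tetragonal": [(2, "41/43", 4), (2, "42", 2), (0, "21", 2), (1, "21", 2)],
    "trigonal": [(2, "31/32", 3)],
    "hexagonal": [(2, "61/65", 6), (2, "62/64", 3), (2, "63", 2)],
    "cubic": [(2, "41/43", 4), (2, "42", 2), (0, "21", 2), (1, "21", 2)],
}


def detect_screw_axes(
    rset: ReflectionSet,
    absent_cut: float = 1.0,
    present_cut: float = 3.0,
    min_class: int = 2,
) -> list[dict]:
    """Screw-axis inference from axial mean I/σ, per principal axis.

    For each screw hypothesis compatible with the crystal family the
    reflections the hypothesis predicts absent are compared with those it
    predicts present; a screw is called when the absent class is at noise
    level (⟨I/σ⟩ < absent_cut) and the present class is significant
    (⟨I/σ⟩ > present_cut).  Per axis, the highest-order passing screw wins.
    """
    hkl = rset.hkl
    I = rset.data["I"].to_numpy(float)
    sig = rset.data["sigI"].to_numpy(float)
    family = rset.sg.crystal_family
    reports = []
    by_axis: dict[int, list[dict]] = {}
    for axis, label, mod in _SCREW_HYPOTHESES.get(family, []):
        others = [i for i in range(3) if i != axis]
        axial = (hkl[:, others[0]] == 0) & (hkl[:, others[1]] == 0) & (hkl[:, axis] != 0)
        if axial.sum() < min_class * 2:
            by_axis.setdefault(axis, []).append(
                dict(axis="abc"[axis], screw=label, verdict="indeterminate",
                     n_axial=int(axial.sum())))
            continue
        idx = np.abs(hkl[axial, axis])
        ios = I[axial] / sig[axial]
        viol = idx % mod != 0
        conf = ~viol
        if viol.sum() < min_class or conf.sum() < min_class:
            entry = dict(axis="abc"[axis], screw=label, verdict="indeterminate",
                         n_axial=int(axial.sum()))
        else:
            mean_v = float(ios[viol].mean())
            mean_c = float(ios[conf].mean())
            present = mean_v < absent_cut and mean_c > present_cut
            entry = dict(
                axis="abc"[axis], screw=label, modulus=mod,
                i_over_sigma_violating=mean_v, i_over_sigma_conforming=mean_c,
                n_violating=int(viol.sum()), n_conforming=int(conf.sum()),
                verdict="screw present" if present else "no screw",
            )
        by_axis.setdefault(axis, []).append(entry)
    for axis, entries in sorted(by_axis.items()):
        passing = [e for e in entries if e.get("verdict") == "screw present"]
        if passing:
            best = max(passing, key=lambda e: e.get("modulus", 0))
            for e in entries:
                if e is not best and e.get("verdict") == "screw present":
                    e["verdict"] = "superseded"
        reports.extend(entries)
    if not reports:
        reports.append(dict(axis=None, screw=None, verdict="indeterminate",
                            note=f"no screw hypotheses for {family} family"))
    return reports


# ---------------------------------------------------------------------------
# R factors


@dataclass
class RFactorResult:
    r_work: float
    r_free: Optional[float]
    scale: float
    n_work: int
    n_free: int


def r_factors(
    f_obs: Sequence[float],
    f_model: Sequence[float],
    free_flags: Optional[Sequence[bool]] = None,
) -> RFactorResult:
    """R = Σ|F_obs − k·F_model| / ΣF_obs on work and free subsets.

    The scale k minimizes the work-set least-squares residual, so the
    result is invariant to uniform rescaling of either input.
    """
    fo = np.asarray(f_obs, dtype=float)
    fm = np.asarray(f_model, dtype=float)
    if fo.shape != fm.shape:
        raise ValueError("F_obs and F_model must have matching length")
    free = (np.zeros(len(fo), dtype=bool) if free_flags is None
            else np.asarray(free_flags, dtype=bool))
    work = ~free
    if work.sum() == 0:
        raise ValueError("empty work set")
    denom = (fm[work] ** 2).sum()
    k = float((fo[work] * fm[work]).sum() / denom) if denom > 0 else 1.0

    def r(mask):
        tot = fo[mask].sum()
        return float(np.abs(fo[mask] - k * fm[mask]).sum() / tot) if tot > 0 else 0.0

    return RFactorResult(
        r_work=r(work),
        r_free=r(free) if free.sum() else None,
        scale=k,
        n_work=int(work.sum()),
        n_free=int(free.sum()),
    )
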