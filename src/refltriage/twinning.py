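"""Twin-law enumeration and twinning diagnostics: L-test, H-test,
Britton plot, detwinning and twin-related intensity correlation.

Candidate twin laws are found by enumerating the point group of the
*lattice* (all small integer matrices that preserve the reciprocal metric
within a tolerance) and reducing it modulo the crystal's own point group
and Friedel symmetry.  Every nontrivial coset representative whose square
folds back into the point group is a candidate twin operator; an exact
metric match in a high-symmetry family is merohedral, a near-match forced
by a special cell metric is pseudo-merohedral.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .reflections import ReflectionSet, asu_map
from .intensity import NormalizedSet
from .symmetry import SpaceGroupOps, UnitCell

__all__ = [
    "TwinLaw", "LTestResult", "HTestResult", "BrittonResult",
    "candidate_twin_laws", "l_test", "h_test", "britton", "detwin",
    "twin_correlation", "l_reference_moments",
]

#: all-even index offsets for L-test pairing (robust to tNCS modulation)
L_TEST_OFFSETS = np.array([
    (0, 0, 2), (0, 2, 0), (2, 0, 0), (0, 2, 2), (2, 0, 2), (2, 2, 0), (2, 2, 2),
])


@dataclass
class TwinLaw:
    operator: np.ndarray  # 3x3 integer, acting on Miller row vectors
    kind: str             # merohedral | pseudo-merohedral | user
    description: str
    metric_deviation: float = 0.0

    def apply(self, hkl: np.ndarray) -> np.ndarray:
        return np.atleast_2d(hkl) @ self.operator

    def hkl_triplet(self) -> str:
        parts = []
        for j in range(3):
            term = ""
            for i, sym in enumerate("hkl"):
                v = self.operator[i, j]
                if v == 0:
                    continue
                sign = "-" if v < 0 else ("+" if term else "")
                term += f"{sign}{sym}" if abs(v) == 1 else f"{sign}{abs(v)}{sym}"
            parts.append(term or "0")
        return ",".join(parts)


def _lattice_point_group(gstar: np.ndarray, tol: float) -> list[np.ndarray]:
    """Integer matrices with entries in {-1,0,1}, det ±1, preserving the
    reciprocal metric within relative tolerance ``tol``."""
    scale = np.sqrt(np.outer(np.diag(gstar), np.diag(gstar)))
    out = []
    for entries in itertools.product((-1, 0, 1), repeat=9):
        m = np.array(entries).reshape(3, 3)
        det = round(float(np.linalg.det(m)))
        if det not in (1, -1):
            continue
        dev = np.abs(m @ gstar @ m.T - gstar) / scale
        if dev.max() < tol:
            out.append(m)
    return out


def candidate_twin_laws(
    cell: UnitCell, sg: SpaceGroupOps, metric_tol: float = 0.02
) -> list[TwinLaw]:
    """Enumerate merohedral / pseudo-merohedral twin laws for this lattice.

    ``metric_tol`` is the relative tolerance on the reciprocal metric
    tensor (the default admits ~0.5° / ~0.5% metric specialization).
    """
    gstar = cell.reciprocal_metric_tensor()
    lattice_ops = _lattice_point_group(gstar, metric_tol)
    group_rots = sg.rotation_stack()
    signed_group = np.concatenate([group_rots, -group_rots])

    def in_group(m: np.ndarray) -> bool:
        return any(np.array_equal(m, g) for g in signed_group)

    scale = np.sqrt(np.outer(np.diag(gstar), np.diag(gstar)))
    high_symmetry = sg.crystal_family in ("tetragonal", "trigonal", "hexagonal", "cubic")
    laws: list[TwinLaw] = []
    claimed: set[bytes] = set()
    for m in lattice_ops:
        if in_group(m) or m.astype(np.int8).tobytes() in claimed:
            continue
        # prefer a representative whose square is a group rotation
        coset = [m @ g for g in group_rots] + [-m @ g for g in group_rots]
        rep = None
        for cand in coset:
            cand = cand.round().astype(int)
            if in_group(cand @ cand):
                rep = cand
                break
        if rep is None:
            continue
        # claim the whole double coset (±G) m (±G): symmetry-composed
        # variants of the same law pair the same reflections
        for g1 in signed_group:
            for g2 in signed_group:
                claimed.add((g1 @ m @ g2).astype(np.int8).tobytes())
        dev = float((np.abs(rep @ gstar @ rep.T - gstar) / scale).max())
        kind = "merohedral" if (high_symmetry and dev < 1e-9) else "pseudo-merohedral"
        order = _op_order(rep)
        if order == 2 and round(float(np.linalg.det(rep))) == 1:
            axis = _twofold_axis(rep)
            desc = f"2-fold along [{axis[0]:g} {axis[1]:g} {axis[2]:g}]"
        else:
            desc = f"order-{order} lattice operation"
        laws.append(TwinLaw(operator=rep, kind=kind, description=desc,
                            metric_deviation=dev))
    laws.sort(key=lambda lw: (lw.metric_deviation, lw.hkl_triplet()))
    return laws


def _op_order(m: np.ndarray) -> int:
    proper = m if round(float(np.linalg.det(m))) == 1 else -m
    acc = np.eye(3, dtype=int)
    for n in range(1, 13):
        acc = acc @ proper
        if np.array_equal(acc, np.eye(3, dtype=int)):
            return n
    return 0


def _twofold_axis(m: np.ndarray) -> np.ndarray:
    _, _, vh = np.linalg.svd((m - np.eye(3)).astype(float))
    axis = vh[-1]
    axis = axis / np.max(np.abs(axis[np.abs(axis) > 1e-6]))
    return np.round(axis, 3)


# ---------------------------------------------------------------------------
# L-test (local intensity differences; robust to tNCS and anisotropy)


@dataclass
class LTestResult:
    mean_abs_L: float
    mean_L2: float
    n_pairs: int
    l_grid: np.ndarray
    cumulative: np.ndarray
    ref_untwinned: np.ndarray
    ref_perfect_twin: np.ndarray
    n_discarded: int = 0


def l_reference_moments(twinned: bool, n: int = 400_000, seed: int = 11) -> dict:
    """MC oracle for L-statistic moments on ideal acentric intensities."""
    rng = np.random.default_rng(seed)
    if twinned:
        i1 = 0.5 * (rng.exponential(size=n) + rng.exponential(size=n))
        i2 = 0.5 * (rng.exponential(size=n) + rng.exponential(size=n))
    else:
        i1 = rng.exponential(size=n)
        i2 = rng.exponential(size=n)
    L = (i1 - i2) / (i1 + i2)
    return {"mean_abs_L": float(np.abs(L).mean()), "mean_L2": float((L**2).mean())}


def l_test(norm: NormalizedSet, seed: int = 0, n_grid: int = 50) -> LTestResult:
    """Padilla–Yeates L-test on normalized intensities.

    Each acentric reflection h is paired with h+δ, with δ drawn per
    reflection (seeded) from the fixed all-even offset set; pairs where a
    member is absent/centric/unmeasured, or where the two reflections are
    symmetry-related, are discarded.  L = (I₁−I₂)/(I₁+I₂) is computed on
    E² values so that resolution falloff cancels.
    """
    df = norm.data
    sg = norm.rset.sg
    usable = (~df["centric"]) & (~df["absent"]) & np.isfinite(df["E2"])
    ac = df[usable]
    if len(ac) < 2000:
        raise ValueError("insufficient pairs: need at least 2000 acentric reflections")
    hkl = ac[["h", "k", "l"]].to_numpy(np.int64)
    E2 = ac["E2"].to_numpy()
    keys = asu_map(hkl, sg, friedel=True)
    lookup = {tuple(k): i for i, k in enumerate(keys)}
    self_key = [tuple(k) for k in keys]

    rng = np.random.default_rng(seed)
    choice = rng.integers(0, len(L_TEST_OFFSETS), size=len(ac))
    partners = asu_map(hkl + L_TEST_OFFSETS[choice], sg, friedel=True)

    l_vals = []
    discarded = 0
    for i, p in enumerate(partners):
        j = lookup.get(tuple(p))
        if j is None or tuple(p) == self_key[i]:
            discarded += 1
            continue
        i1, i2 = E2[i], E2[j]
        tot = i1 + i2
        if not np.isfinite(tot) or tot <= 0:
            discarded += 1
            continue
        l_vals.append((i1 - i2) / tot)
    if len(l_vals) < 200:
        raise ValueError("insufficient pairs: fewer than 200 L-test pairs survive")
    L = np.array(l_vals)
    absL = np.abs(L)
    grid = np.linspace(1.0 / n_grid, 1.0, n_grid)
    cum = np.array([(absL <= g).mean() for g in grid])
    return LTestResult(
        mean_abs_L=float(absL.mean()),
        mean_L2=float((L**2).mean()),
        n_pairs=len(L),
        l_grid=grid,
        cumulative=cum,
        ref_untwinned=grid.copy(),
        ref_perfect_twin=grid * (3.0 - grid**2) / 2.0,
        n_discarded=discarded,
    )


# ---------------------------------------------------------------------------
# Twin-related pairs


def _twin_pairs(rset: ReflectionSet, law: TwinLaw):
    """Matched acentric twin-related intensity pairs (I1, I2), each unique
    unordered pair once, symmetry-degenerate pairs excluded."""
    if not rset.merged:
        raise ValueError("twin statistics expect a merged set")
    _, centric, absent = rset.classify()
    good = (~centric) & (~absent)
    hkl = rset.hkl[good]
    I = rset.data["I"].to_numpy(float)[good]
    sig = rset.data["sigI"].to_numpy(float)[good]
    keys = asu_map(hkl, rset.sg, friedel=True)
    lookup = {tuple(k): i for i, k in enumerate(keys)}
    partners = asu_map(law.apply(hkl), rset.sg, friedel=True)
    i1_idx, i2_idx = [], []
    seen = set()
    for i, p in enumerate(partners):
        tp = tuple(p)
        ts = tuple(keys[i])
        if tp == ts:
            continue  # reflection fixed by the law: degenerate
        j = lookup.get(tp)
        if j is None:
            continue
        pair_key = (ts, tp) if ts > tp else (tp, ts)
        if pair_key in seen:
            continue
        seen.add(pair_key)
        i1_idx.append(i)
        i2_idx.append(j)
    return (I[i1_idx], I[i2_idx], sig[i1_idx], sig[i2_idx],
            np.flatnonzero(good)[i1_idx], np.flatnonzero(good)[i2_idx])


@dataclass
class HTestResult:
    alpha_mean: float
    alpha_slope: float
    n_pairs: int
    n_excluded: int


def h_test(rset: ReflectionSet, law: TwinLaw, min_pairs: int = 500) -> HTestResult:
    """Yeates H-test: H = |I₁−I₂|/(I₁+I₂) over twin-related pairs.

    For twin fraction α the cumulative distribution of H is
    S(H) = H/(1−2α) on [0, 1−2α], hence ⟨H⟩ = (1−2α)/2 and
    α = 1/2 − ⟨H⟩; a slope fit of S(H) through the origin gives an
    independent estimate.
    """
    I1, I2, *_ = _twin_pairs(rset, law)
    tot = I1 + I2
    ok = tot > 0
    n_excluded = int((~ok).sum())
    H = np.abs(I1[ok] - I2[ok]) / tot[ok]
    if len(H) < min_pairs:
        raise ValueError(f"insufficient pairs: {len(H)} twin-related pairs")
    alpha_mean = float(np.clip(0.5 - H.mean(), 0.0, 0.5))
    # cumulative slope over the linear region (S <= 0.8)
    hs = np.sort(H)
    S = (np.arange(len(hs)) + 1) / len(hs)
    lin = S <= 0.8
    if lin.sum() >= 10 and (hs[lin] ** 2).sum() > 0:
        slope = float((S[lin] * hs[lin]).sum() / (hs[lin] ** 2).sum())
        alpha_slope = float(np.clip((slope - 1.0) / (2.0 * slope), 0.0, 0.5)) \
            if slope > 0 else 0.0
    else:
        alpha_slope = alpha_mean
    return HTestResult(alpha_mean=alpha_mean, alpha_slope=alpha_slope,
                       n_pairs=int(len(H)), n_excluded=n_excluded)


@dataclass
class BrittonResult:
    alpha_grid: np.ndarray
    n_negative: np.ndarray
    alpha_estimate: float
    flagged: bool = False


def britton(rset: ReflectionSet, law: TwinLaw, grid_step: float = 0.01,
            min_pairs: int = 500) -> BrittonResult:
    """Britton plot: negative detwinned intensities vs trial twin fraction.

    Detwinning with a trial α above the true twin fraction drives some
    intensities negative; the α-axis intercept of the rising part of the
    negative-count curve estimates the twin fraction.
    """
    I1, I2, *_ = _twin_pairs(rset, law)
    if len(I1) < min_pairs:
        raise ValueError(f"insufficient pairs: {len(I1)} twin-related pairs")
    alphas = np.arange(0.0, 0.495, grid_step)
    counts = np.empty(len(alphas), dtype=int)
    for i, a in enumerate(alphas):
        d1 = (1 - a) * I1 - a * I2
        d2 = (1 - a) * I2 - a * I1
        counts[i] = int((d1 < 0).sum() + (d2 < 0).sum())
    cmax = counts.max()
    if cmax == 0:
        return BrittonResult(alphas, counts, 0.0, flagged=True)
    rising = (counts >= 0.10 * cmax) & (counts <= 0.60 * cmax)
    if rising.sum() < 2:
        return BrittonResult(alphas, counts, 0.0, flagged=True)
    slope, intercept = np.polyfit(alphas[rising], counts[rising].astype(float), 1)
    est = -intercept / slope if slope > 0 else 0.0
    return BrittonResult(alphas, counts, float(np.clip(est, 0.0, 0.4999)))


def detwin(rset: ReflectionSet, law: TwinLaw, alpha: float) -> ReflectionSet:
    """Algebraic detwinning: I₁′ = ((1−α)I₁ − αI₂)/(1−2α), σ propagated in
    quadrature.  Reflections whose twin mate is missing are left unchanged
    (their count is stored on the result as ``n_unpaired``)."""
    if not 0.0 <= alpha < 0.5:
        raise ValueError("detwinning singular: alpha must be in [0, 0.5)")
    df = rset.data.copy()
    if alpha == 0.0:
        out = rset.with_data(df)
        out.n_unpaired = 0
        return out
    I = df["I"].to_numpy(float).copy()
    sig = df["sigI"].to_numpy(float).copy()
    hkl = rset.hkl
    keys = asu_map(hkl, rset.sg, friedel=not rset.anomalous)
    lookup = {tuple(k): i for i, k in enumerate(keys)}
    partners = asu_map(law.apply(hkl), rset.sg, friedel=not rset.anomalous)
    part_idx = np.array([lookup.get(tuple(p), -1) for p in partners])
    self_match = np.array([tuple(p) == tuple(k) for p, k in zip(partners, keys)])
    paired = (part_idx >= 0) & (~self_match)
    denom = 1.0 - 2.0 * alpha
    I_new = I.copy()
    sig_new = sig.copy()
    j = part_idx[paired]
    I_new[paired] = ((1 - alpha) * I[paired] - alpha * I[j]) / denom
    sig_new[paired] = np.sqrt(((1 - alpha) * sig[paired]) ** 2 +
                              (alpha * sig[j]) ** 2) / denom
    df["I"] = I_new
    df["sigI"] = sig_new
    out = rset.with_data(df)
    out.n_unpaired = int((~paired).sum())
    return out


def twin_correlation(rset: ReflectionSet, law: TwinLaw,
                     min_pairs: int = 100) -> dict:
    """Pearson correlation of twin-related intensity pairs, with the
    merging-R the pairs would have under the symmetry augmented by the law.

    Correlation near 1 together with a small augmented-symmetry R points
    at under-assigned symmetry rather than twinning.
    """
    from .intensity import normalize  # deferred: avoids import cycle

    I1, I2, _, _, idx1, idx2 = _twin_pairs(rset, law)
    if len(I1) < min_pairs:
        raise ValueError(f"insufficient pairs: {len(I1)}")
    # correlate shell-normalized intensities so the common resolution
    # falloff does not masquerade as twin correlation
    E2 = normalize(rset).data["E2"].to_numpy()
    e1, e2 = E2[idx1], E2[idx2]
    ok = np.isfinite(e1) & np.isfinite(e2)
    r = float(stats.pearsonr(e1[ok], e2[ok]).statistic)
    denom = np.abs(I1 + I2).sum()
    r_aug = float(np.abs(I1 - I2).sum() / denom) if denom > 0 else np.nan
    return {"correlation": r, "r_augmented": r_aug, "n_pairs": int(len(I1))}
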