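"""Synthetic diffraction data with known ground truth.

Random atomic structures are expanded to P1 with the space-group
operators, structure factors are computed by direct summation with
4-Gaussian form factors and isotropic (or a global anisotropic)
Debye–Waller factors, and the pathologies under test — twinning by a
chosen law, translational NCS, anomalous scattering, Gaussian
counting-like noise — are injected with exactly known parameters.

Amplitude Debye–Waller convention: exp(−B s²) with s² = 1/(4d²), i.e.
exp(−B/(4d²)), matching the Wilson-fit convention of
:mod:`refltriage.intensity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
import pandas as pd

from .formfactors import PROTEIN_FRACTIONS, electron_count, f0
from .reflections import ReflectionSet, asu_map, write_reflections
from .symmetry import SpaceGroupOps, UnitCell, parse_spacegroup
from .twinning import TwinLaw, candidate_twin_laws

__all__ = [
    "AtomSite", "StructureFactorSet", "SyntheticConfig", "SyntheticDataset",
    "generate_structure", "calc_structure_factors", "apply_twin", "add_noise",
    "simulate_dataset",
]


@dataclass
class AtomSite:
    element: str
    frac: tuple[float, float, float]
    B: float = 20.0
    occ: float = 1.0

    def __post_init__(self):
        if self.B < 0:
            raise ValueError("B must be >= 0")
        if not 0.0 < self.occ <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")


@dataclass
class StructureFactorSet:
    hkl: np.ndarray              # (n, 3) canonical unique indices
    F: np.ndarray                # complex structure factors (mean of mates)
    F_plus: Optional[np.ndarray] = None
    F_minus: Optional[np.ndarray] = None

    @property
    def I(self) -> np.ndarray:
        return np.abs(self.F) ** 2

    @property
    def I_plus(self) -> Optional[np.ndarray]:
        return None if self.F_plus is None else np.abs(self.F_plus) ** 2

    @property
    def I_minus(self) -> Optional[np.ndarray]:
        return None if self.F_minus is None else np.abs(self.F_minus) ** 2


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one simulated dataset."""

    seed: int
    cell: tuple[float, ...] = (40.0, 48.0, 56.0, 90.0, 100.0, 90.0)
    sg_symbol: str = "P21"
    n_atoms: int = 150
    element_fractions: dict[str, float] = field(
        default_factory=lambda: dict(PROTEIN_FRACTIONS))
    b_range: tuple[float, float] = (15.0, 25.0)
    b_tensor: Optional[tuple[float, ...]] = None  # 6 components B11,B22,B33,B12,B13,B23
    d_min: float = 2.0
    alpha_true: float = 0.0
    twin_law: Optional[list[list[int]]] = None  # explicit operator, else auto
    tncs_vector: Optional[tuple[float, float, float]] = None
    f_double_prime: dict[str, float] = field(default_factory=dict)
    noise_k: float = 0.03

    def __post_init__(self):
        if not 0.0 <= self.alpha_true <= 0.5:
            raise ValueError("alpha_true must be in [0, 0.5]")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def unit_cell(self) -> UnitCell:
        return UnitCell(*self.cell)

    def spacegroup(self) -> SpaceGroupOps:
        return parse_spacegroup(self.sg_symbol)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    atoms: list[AtomSite]            # asymmetric unit (tNCS copies included)
    expanded_atoms: list[AtomSite]   # P1 expansion actually used for F calc
    true_sf: StructureFactorSet
    true_intensity: np.ndarray       # after twinning, before noise
    reflections: ReflectionSet       # observed (noisy) merged set
    twin_law: Optional[TwinLaw]
    files: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------


def generate_structure(config: SyntheticConfig) -> tuple[list[AtomSite], list[AtomSite]]:
    """Random atoms in the asymmetric unit, tNCS-duplicated and
    symmetry-expanded to P1.  Returns (asymmetric unit, P1 expansion)."""
    if config.n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(config.seed)
    elements = list(config.element_fractions)
    probs = np.array([config.element_fractions[e] for e in elements], dtype=float)
    probs /= probs.sum()
    chosen = rng.choice(len(elements), size=config.n_atoms, p=probs)
    coords = rng.random((config.n_atoms, 3))
    b_lo, b_hi = config.b_range
    bvals = rng.uniform(b_lo, b_hi, size=config.n_atoms)
    asym = [
        AtomSite(element=elements[c], frac=tuple(x), B=float(b))
        for c, x, b in zip(chosen, coords, bvals)
    ]
    if config.tncs_vector is not None:
        t = np.asarray(config.tncs_vector, dtype=float)
        asym += [
            AtomSite(element=a.element,
                     frac=tuple(np.mod(np.array(a.frac) + t, 1.0)),
                     B=a.B, occ=a.occ)
            for a in asym
        ]
    sg = config.spacegroup()
    expanded = []
    for op in sg.ops:
        rot = op.rot
        tran = np.array([float(t) for t in op.translation])
        for a in asym:
            x = np.mod(rot @ np.array(a.frac) + tran, 1.0)
            expanded.append(AtomSite(element=a.element, frac=tuple(x), B=a.B, occ=a.occ))
    return asym, expanded


def _dw_factors(atoms_B: np.ndarray, s2: np.ndarray) -> np.ndarray:
    return np.exp(-np.outer(s2, atoms_B))


def calc_structure_factors(
    atoms: list[AtomSite],
    hkl: np.ndarray,
    cell: UnitCell,
    f_double_prime: Optional[dict[str, float]] = None,
    b_tensor: Optional[np.ndarray] = None,
    chunk: int = 4096,
) -> StructureFactorSet:
    """Direct-summation structure factors F(h) = Σ_j occ f_j DW_j e^{2πi h·x}.

    With anomalous corrections (f = f0 + i f″) Friedel symmetry breaks and
    F⁺, F⁻ are computed from +h and −h separately.
    """
    if not atoms or not len(hkl):
        raise ValueError("need non-empty atom and reflection lists")
    f_double_prime = f_double_prime or {}
    hkl = np.asarray(hkl, dtype=int)
    # a supplied f" map requests Bijvoet-separated output even when all
    # values are zero (the pure-noise null of the measurability statistic)
    anomalous = bool(f_double_prime)
    frac = np.array([a.frac for a in atoms])
    occ = np.array([a.occ for a in atoms])
    bval = np.array([a.B for a in atoms])
    elements = np.array([a.element for a in atoms])
    uniq_elements = sorted(set(elements))
    for el in uniq_elements:
        f0(el, np.zeros(1), fallback_z=None if el in ("H", "C", "N", "O", "P", "S")
           else electron_count(el))  # raises early for unknown elements

    d = cell.d_values(hkl)
    s2 = 1.0 / (4.0 * d**2)
    aniso = None
    if b_tensor is not None:
        bt = np.asarray(b_tensor, dtype=float)
        if bt.shape == (6,):
            b11, b22, b33, b12, b13, b23 = bt
            bt = np.array([[b11, b12, b13], [b12, b22, b23], [b13, b23, b33]])
        svec = cell.reciprocal_cartesian(hkl)
        aniso = np.exp(-0.25 * np.einsum("ni,ij,nj->n", svec, bt, svec))

    def sf_for(h_arr, s2_arr):
        F = np.zeros(len(h_arr), dtype=complex)
        for el in uniq_elements:
            mask = elements == el
            f_el = f0(el, s2_arr).astype(complex)
            fdp = f_double_prime.get(el, 0.0)
            if fdp:
                f_el = f_el + 1j * fdp
            for start in range(0, len(h_arr), chunk):
                sl = slice(start, start + chunk)
                phases = np.exp(2j * np.pi * (h_arr[sl].astype(float) @ frac[mask].T))
                dw = _dw_factors(bval[mask], s2_arr[sl])
                F[sl] += (phases * dw * occ[mask][None, :]).sum(axis=1) * f_el[sl]
        return F

    F_plus = sf_for(hkl, s2)
    if aniso is not None:
        F_plus = F_plus * aniso
    if anomalous:
        F_minus = sf_for(-hkl, s2)
        if aniso is not None:
            F_minus = F_minus * aniso
        F_mean = 0.5 * (F_plus + np.conj(F_minus))
        return StructureFactorSet(hkl=hkl, F=F_mean, F_plus=F_plus, F_minus=F_minus)
    return StructureFactorSet(hkl=hkl, F=F_plus)


def apply_twin(I: np.ndarray, hkl: np.ndarray, law: TwinLaw, alpha: float,
               sg: SpaceGroupOps, anomalous: bool = False):
    """I_obs(h) = (1−α)·I(h) + α·I(T·h).

    Returns (I_twinned, kept_mask); reflections whose twin mate falls
    outside the index set are dropped and counted via the mask.
    """
    if not 0.0 <= alpha <= 0.5:
        raise ValueError("alpha must be in [0, 0.5]")
    if alpha == 0.0:
        return I.copy(), np.ones(len(I), dtype=bool)
    keys = asu_map(hkl, sg, friedel=not anomalous)
    lookup = {tuple(k): i for i, k in enumerate(keys)}
    partners = asu_map(law.apply(hkl), sg, friedel=not anomalous)
    part_idx = np.array([lookup.get(tuple(p), -1) for p in partners])
    kept = part_idx >= 0
    out = I.copy()
    out[kept] = (1.0 - alpha) * I[kept] + alpha * I[part_idx[kept]]
    return out, kept


def add_noise(I: np.ndarray, noise_k: float, seed: int):
    """Gaussian counting-like noise: σ(h) = k·√(max(I, ⟨I⟩/100)·⟨I⟩).

    Negative noisy intensities are retained.  With k = 0 the intensities
    are returned unchanged with a tiny floor σ so that σ > 0 always holds.
    """
    if noise_k < 0:
        raise ValueError("noise_k must be >= 0")
    I = np.asarray(I, dtype=float)
    mean_I = max(float(I.mean()), 1e-300)
    k_eff = max(noise_k, 1e-6)
    sig = k_eff * np.sqrt(np.maximum(I, mean_I / 100.0) * mean_I)
    rng = np.random.default_rng(seed)
    if noise_k > 0:
        I_obs = I + rng.normal(0.0, 1.0, size=len(I)) * sig
    else:
        I_obs = I.copy()
    return I_obs, sig


def enumerate_unique_hkl(cell: UnitCell, sg: SpaceGroupOps, d_min: float,
                         friedel: bool = True) -> np.ndarray:
    """Canonical unique Miller indices to d_min (absences included)."""
    limits = [int(np.floor(L / d_min)) + 1 for L in (cell.a, cell.b, cell.c)]
    axes = [np.arange(-n, n + 1) for n in limits]
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    grid = grid[np.any(grid != 0, axis=1)]
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ij,jk,ik->i", grid.astype(float), gstar, grid.astype(float))
    keep = inv_d2 <= 1.0 / d_min**2
    grid = grid[keep]
    uniq = np.unique(asu_map(grid, sg, friedel=friedel), axis=0)
    return uniq


def simulate_dataset(config: SyntheticConfig, out_dir: Optional[Path] = None) -> SyntheticDataset:
    """Full pipeline: structure → unique hkl → direct-summation F →
    twinning → noise → observed :class:`ReflectionSet` (+ optional files)."""
    cell = config.unit_cell()
    sg = config.spacegroup()
    anomalous = bool(config.f_double_prime)

    law = None
    if config.alpha_true > 0:
        if config.twin_law is not None:
            op = np.asarray(config.twin_law, dtype=int)
            law = TwinLaw(operator=op, kind="user", description="user-supplied")
            cand = candidate_twin_laws(cell, sg)
            if not any(np.array_equal(op, c.operator) for c in cand):
                # still accept if it maps the lattice to itself
                gstar = cell.reciprocal_metric_tensor()
                scale = np.sqrt(np.outer(np.diag(gstar), np.diag(gstar)))
                if (np.abs(op @ gstar @ op.T - gstar) / scale).max() > 0.02:
                    raise ValueError("twin law invalid for this lattice")
        else:
            cand = candidate_twin_laws(cell, sg)
            if not cand:
                raise ValueError(
                    f"no twin law available for {config.sg_symbol} with this cell")
            law = cand[0]

    asym, expanded = generate_structure(config)
    b_tensor = np.asarray(config.b_tensor, dtype=float) if config.b_tensor is not None else None
    # unique Friedel-collapsed indices; Bijvoet mates live in the
    # Iplus/Iminus columns when anomalous scatterers are present
    hkl = enumerate_unique_hkl(cell, sg, config.d_min, friedel=True)
    sf = calc_structure_factors(expanded, hkl, cell,
                                f_double_prime=config.f_double_prime,
                                b_tensor=b_tensor)

    rng_seed = np.random.default_rng(config.seed)
    noise_seed = int(rng_seed.integers(0, 2**31 - 1))

    if anomalous:
        I_p, kept_p = (sf.I_plus, np.ones(len(hkl), bool))
        I_m = sf.I_minus
        if law is not None:
            # mates mix within the same Bijvoet column (adequate at the
            # small anomalous differences simulated here)
            I_p, kept_p = apply_twin(sf.I_plus, hkl, law, config.alpha_true, sg)
            I_m, kept_m = apply_twin(sf.I_minus, hkl, law, config.alpha_true, sg)
            kept_p &= kept_m
        hkl_k = hkl[kept_p]
        I_p, I_m = I_p[kept_p], I_m[kept_p]
        true_I = 0.5 * (I_p + I_m)
        Ip_obs, sig_p = add_noise(I_p, config.noise_k, noise_seed)
        Im_obs, sig_m = add_noise(I_m, config.noise_k, noise_seed + 1)
        df = pd.DataFrame({
            "h": hkl_k[:, 0], "k": hkl_k[:, 1], "l": hkl_k[:, 2],
            "I": 0.5 * (Ip_obs + Im_obs),
            "sigI": 0.5 * np.sqrt(sig_p**2 + sig_m**2),
            "Iplus": Ip_obs, "sigIplus": sig_p,
            "Iminus": Im_obs, "sigIminus": sig_m,
        })
    else:
        true_I, kept = sf.I, np.ones(len(hkl), bool)
        if law is not None:
            true_I, kept = apply_twin(sf.I, hkl, law, config.alpha_true, sg)
        hkl_k = hkl[kept]
        true_I = true_I[kept]
        I_obs, sig = add_noise(true_I, config.noise_k, noise_seed)
        df = pd.DataFrame({
            "h": hkl_k[:, 0], "k": hkl_k[:, 1], "l": hkl_k[:, 2],
            "I": I_obs, "sigI": sig,
        })

    rset = ReflectionSet(cell=cell, sg=sg, data=df, merged=True, anomalous=anomalous)
    files = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files["csv"] = write_reflections(rset, out_dir / "reflections.csv", "csv")
        files["mmcif"] = write_reflections(rset, out_dir / "reflections.cif", "mmcif")
        files["pdb"] = _write_pdb(asym, cell, sg, out_dir / "model.pdb")
    return SyntheticDataset(
        config=config, atoms=asym, expanded_atoms=expanded, true_sf=sf,
        true_intensity=true_I, reflections=rset, twin_law=law, files=files,
    )


def _write_pdb(atoms: list[AtomSite], cell: UnitCell, sg: SpaceGroupOps, path: Path) -> Path:
    st = gemmi.Structure()
    st.name = "synthetic"
    st.cell = cell.to_gemmi()
    st.spacegroup_hm = sg.symbol
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    ortho = cell.orthogonalization_matrix()
    for i, a in enumerate(atoms, start=1):
        res = gemmi.Residue()
        res.name = "DUM"
        res.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = a.element
        atom.element = gemmi.Element(a.element)
        xyz = ortho @ np.array(a.frac)
        atom.pos = gemmi.Position(*xyz)
        atom.occ = a.occ
        atom.b_iso = a.B
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path
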