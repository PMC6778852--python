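"""Unit-cell metric algebra and space-group operator machinery.

Conventions used throughout the package:

* Miller indices act as *row* vectors on the rotation matrix of a
  symmetry operation: ``h' = h @ R``.  With coordinate columns the same
  matrix maps fractional positions, ``x' = R @ x + t``, so the phase
  ``h . x`` is preserved between the two actions.
* Translations are exact :class:`fractions.Fraction` triples reduced to
  ``[0, 1)``.
* Lattice centring (C, I, F) is represented by including the centring
  translations as ordinary group elements, which makes systematic-absence
  and merging logic uniform across settings.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymOp",
    "SpaceGroupOps",
    "SUPPORTED_SYMBOLS",
    "parse_spacegroup",
    "d_spacing",
    "epsilon_factor",
    "is_centric",
    "is_absent",
]


# ---------------------------------------------------------------------------
# Unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic-general unit cell (lengths in Å, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (Å²)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())

    @property
    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Columns are the cell basis vectors in a Cartesian frame (Å)."""
        g = self.metric_tensor()
        return np.linalg.cholesky(g).T  # upper triangular, a along x

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ np.linalg.inv(self.orthogonalization_matrix()).T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orthogonalization_matrix().T

    def reciprocal_cartesian(self, hkl: np.ndarray) -> np.ndarray:
        """Reciprocal-space vectors h·a* + k·b* + l·c* in Cartesian Å⁻¹."""
        return np.atleast_2d(hkl) @ np.linalg.inv(self.orthogonalization_matrix())

    def d_values(self, hkl: np.ndarray) -> np.ndarray:
        """d-spacings (Å) for an (n, 3) array of Miller indices."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        gstar = self.reciprocal_metric_tensor()
        inv_d2 = np.einsum("ij,jk,ik->i", h, gstar, h)
        if np.any(inv_d2 <= 0):
            raise ValueError("undefined d-spacing for hkl = (0,0,0)")
        return 1.0 / np.sqrt(inv_d2)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def d_spacing(hkl: Sequence[int], cell: UnitCell) -> float:
    """Resolution of one reflection in Å; raises for (0,0,0)."""
    if tuple(hkl) == (0, 0, 0):
        raise ValueError("undefined d-spacing for hkl = (0,0,0)")
    return float(cell.d_values(np.asarray(hkl)[None, :])[0])


# ---------------------------------------------------------------------------
# Symmetry operations


def _frac_mod1(x: Fraction) -> Fraction:
    return x - Fraction(math.floor(x))


@dataclass(frozen=True)
class SymOp:
    """One symmetry operation: integer rotation + fractional translation."""

    rotation: tuple[tuple[int, ...], ...]
    translation: tuple[Fraction, Fraction, Fraction]

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.rotation, dtype=int)

    @classmethod
    def from_arrays(cls, rot: np.ndarray, tran: Iterable[Fraction]) -> "SymOp":
        rot = np.asarray(rot, dtype=int)
        det = round(float(np.linalg.det(rot)))
        if det not in (1, -1):
            raise ValueError("rotation determinant must be +1 or -1")
        if np.any(np.abs(rot) > 1):
            raise ValueError("rotation entries must be in {-1, 0, 1}")
        tran = tuple(_frac_mod1(Fraction(t)) for t in tran)
        return cls(tuple(tuple(int(v) for v in row) for row in rot), tran)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        # hand-rolled so arbitrary fraction denominators are accepted
        parts = triplet.replace(" ", "").lower().split(",")
        if len(parts) != 3:
            raise ValueError(f"malformed triplet {triplet!r}")
        rot = np.zeros((3, 3), dtype=int)
        tran = [Fraction(0)] * 3
        token_re = re.compile(r"([+-]?)(\d+/\d+|\d+(?:\.\d+)?|[xyz])")
        for i, part in enumerate(parts):
            consumed = 0
            for m in token_re.finditer(part):
                if m.start() != consumed:
                    raise ValueError(f"malformed triplet component {part!r}")
                consumed = m.end()
                sign = -1 if m.group(1) == "-" else 1
                tok = m.group(2)
                if tok in "xyz":
                    rot[i, "xyz".index(tok)] += sign
                else:
                    tran[i] += sign * Fraction(tok)
            if consumed != len(part):
                raise ValueError(f"malformed triplet component {part!r}")
        return cls.from_arrays(rot, tran)

    def triplet(self) -> str:
        parts = []
        for i in range(3):
            term = ""
            for j, axis in enumerate("xyz"):
                r = self.rotation[i][j]
                if r == 0:
                    continue
                sign = "-" if r < 0 else ("+" if term else "")
                term += f"{sign}{axis}"
            t = self.translation[i]
            if t != 0:
                term += f"+{t.numerator}/{t.denominator}"
            parts.append(term or "0")
        return ",".join(parts)

    def __mul__(self, other: "SymOp") -> "SymOp":
        r1, r2 = self.rot, other.rot
        t = tuple(
            _frac_mod1(
                sum(Fraction(int(r1[i, j])) * other.translation[j] for j in range(3))
                + self.translation[i]
            )
            for i in range(3)
        )
        return SymOp.from_arrays(r1 @ r2, t)

    def apply_to_hkl(self, hkl: Sequence[int]) -> tuple[int, int, int]:
        h = np.asarray(hkl, dtype=int) @ self.rot
        return tuple(int(v) for v in h)

    def phase_shift(self, hkl: Sequence[int]) -> Fraction:
        """h · t, as an exact fraction."""
        return sum(Fraction(int(h)) * t for h, t in zip(hkl, self.translation))

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.rot, np.eye(3, dtype=int)) and all(
            t == 0 for t in self.translation
        )


IDENTITY = SymOp.from_arrays(np.eye(3, dtype=int), (Fraction(0),) * 3)

# Symbols accepted by name; anything else must come in as explicit triplets.
SUPPORTED_SYMBOLS = (
    "P1", "P-1", "P2", "P21", "C2", "P222", "P212121", "C2221",
    "P4", "P41", "P41212", "P3", "P31", "P3121", "P6", "P61",
    "P213", "I213",
)

_FAMILIES = ("triclinic", "monoclinic", "orthorhombic", "tetragonal",
             "trigonal", "hexagonal", "cubic")


def _proper_order_and_axis(rot: np.ndarray) -> tuple[int, np.ndarray | None]:
    """Order of the proper part of a rotation, and its axis for order ≥ 2."""
    proper = rot if round(float(np.linalg.det(rot))) == 1 else -rot
    acc = np.eye(3, dtype=int)
    for n in range(1, 7):
        acc = acc @ proper
        if np.array_equal(acc, np.eye(3, dtype=int)):
            if n == 1:
                return 1, None
            # axis: null vector of (proper - I)
            m = proper - np.eye(3, dtype=int)
            _, _, vh = np.linalg.svd(m.astype(float))
            axis = vh[-1]
            axis = axis / np.max(np.abs(axis))
            return n, np.round(axis, 6)
    raise ValueError("rotation has order > 6; not crystallographic")


def _crystal_family(rotations: list[np.ndarray]) -> str:
    orders = []
    axes_by_order: dict[int, list[tuple]] = {}
    for rot in rotations:
        n, axis = _proper_order_and_axis(rot)
        orders.append(n)
        if n >= 2 and axis is not None:
            # canonicalize the axis sign (±v are the same axis) without
            # collapsing distinct body diagonals
            v = np.round(axis, 4)
            nz = np.flatnonzero(np.abs(v) > 1e-6)
            if len(nz) and v[nz[0]] < 0:
                v = -v
            key = tuple(v)
            axes_by_order.setdefault(n, [])
            if key not in axes_by_order[n]:
                axes_by_order[n].append(key)
    threefold_axes = len(axes_by_order.get(3, []))
    if threefold_axes >= 2:
        return "cubic"
    if 6 in orders:
        return "hexagonal"
    if 4 in orders:
        return "tetragonal"
    if 3 in orders:
        return "trigonal"
    twofold_axes = len(axes_by_order.get(2, []))
    if twofold_axes >= 2:
        return "orthorhombic"
    if twofold_axes == 1:
        return "monoclinic"
    return "triclinic"


@dataclass
class SpaceGroupOps:
    """A closed set of symmetry operations with derived metadata."""

    symbol: str
    ops: list[SymOp]
    crystal_family: str = field(default="")

    def __post_init__(self):
        if not any(op.is_identity for op in self.ops):
            raise ValueError("group does not contain the identity")
        if len(self.ops) > 192 or 192 % len(self.ops):
            raise ValueError("group order must divide 192")
        if not self.crystal_family:
            self.crystal_family = _crystal_family([op.rot for op in self.ops])

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self):
        return iter(self.ops)

    def triplets(self) -> list[str]:
        return [op.triplet() for op in self.ops]

    def distinct_rotations(self) -> list[np.ndarray]:
        seen, out = set(), []
        for op in self.ops:
            key = tuple(map(tuple, op.rotation))
            if key not in seen:
                seen.add(key)
                out.append(op.rot)
        return out

    def rotation_stack(self) -> np.ndarray:
        """(m, 3, 3) array of the distinct rotation matrices."""
        return np.stack(self.distinct_rotations())

    @property
    def is_centrosymmetric(self) -> bool:
        neg = -np.eye(3, dtype=int)
        return any(np.array_equal(r, neg) for r in self.distinct_rotations())

    def to_gemmi(self) -> gemmi.SpaceGroup | None:
        try:
            return gemmi.SpaceGroup(self.symbol)
        except Exception:
            return None


def _close_group(generators: list[SymOp], symbol: str) -> SpaceGroupOps:
    ops: dict[tuple, SymOp] = {}

    def key(op: SymOp):
        return (op.rotation, op.translation)

    frontier = [IDENTITY] + list(generators)
    for op in frontier:
        ops[key(op)] = op
    changed = True
    while changed:
        changed = False
        current = list(ops.values())
        for a in current:
            for b in current:
                c = a * b
                k = key(c)
                if k not in ops:
                    ops[k] = c
                    changed = True
                    if len(ops) > 192:
                        raise ValueError("not a group: closure exceeds order 192")
    if 192 % len(ops):
        raise ValueError(f"not a group: order {len(ops)} is not crystallographic")
    return SpaceGroupOps(symbol=symbol, ops=list(ops.values()))


def _normalize_symbol(symbol: str) -> str:
    s = symbol.replace(" ", "").replace("_", "")
    return s[:1].upper() + s[1:]


def parse_spacegroup(spec: str | Sequence[str]) -> SpaceGroupOps:
    """Build a :class:`SpaceGroupOps` from a symbol or triplet strings.

    Symbols are limited to :data:`SUPPORTED_SYMBOLS`; any other setting
    must be supplied as explicit ``"x,y,z"``-style triplets, which are
    closed under composition (an input that fails to close is rejected).
    """
    if isinstance(spec, str):
        symbol = _normalize_symbol(spec)
        if symbol not in SUPPORTED_SYMBOLS:
            raise ValueError(f"unsupported space group: {spec!r}")
        gsg = gemmi.SpaceGroup(symbol)
        ops = [
            SymOp.from_arrays(
                np.array(op.rot, dtype=int) // gemmi.Op.DEN,
                (Fraction(t, gemmi.Op.DEN) for t in op.tran),
            )
            for op in gsg.operations()
        ]
        return SpaceGroupOps(symbol=symbol, ops=ops)
    triplets = list(spec)
    if not triplets:
        raise ValueError("empty triplet list")
    generators = [SymOp.from_triplet(t) for t in triplets]
    group = _close_group(generators, symbol=f"custom[{';'.join(triplets)}]")
    return group


# ---------------------------------------------------------------------------
# Reflection classification


def epsilon_factor(hkl: Sequence[int], sg: SpaceGroupOps) -> int:
    """Symmetry-enhancement factor ε: rotations leaving hkl fixed (row action)."""
    h = np.asarray(hkl, dtype=int)
    return int(sum(np.array_equal(h @ r, h) for r in sg.distinct_rotations()))


def is_centric(hkl: Sequence[int], sg: SpaceGroupOps) -> bool:
    """True iff some rotation of the group maps hkl to −hkl."""
    h = np.asarray(hkl, dtype=int)
    return any(np.array_equal(h @ r, -h) for r in sg.distinct_rotations())


def is_absent(hkl: Sequence[int], sg: SpaceGroupOps) -> bool:
    """Systematic absence: an op fixes hkl by rotation with non-integer h·t."""
    h = np.asarray(hkl, dtype=int)
    for op in sg.ops:
        if np.array_equal(h @ op.rot, h) and op.phase_shift(h) % 1 != 0:
            return True
    return False


# Vectorized counterparts used by the heavier modules ------------------------


def classify_reflections(hkl: np.ndarray, sg: SpaceGroupOps):
    """Vectorized (epsilon, centric, absent) for an (n, 3) index array."""
    hkl = np.asarray(hkl, dtype=int)
    n = len(hkl)
    rots = sg.rotation_stack()
    mapped = np.einsum("nj,mjk->mnk", hkl, rots)  # (m, n, 3)
    fixed = np.all(mapped == hkl[None, :, :], axis=2)  # (m, n)
    eps = fixed.sum(axis=0).astype(int)
    centric = np.any(np.all(mapped == -hkl[None, :, :], axis=2), axis=0)
    absent = np.zeros(n, dtype=bool)
    for op in sg.ops:
        t = np.array([float(x) for x in op.translation])
        if not t.any():
            continue
        fixed_op = np.all(hkl @ op.rot == hkl, axis=1)
        if not fixed_op.any():
            continue
        ht = hkl[fixed_op].astype(float) @ t
        frac = np.abs(ht - np.round(ht))
        bad = frac > 1e-9
        idx = np.flatnonzero(fixed_op)
        absent[idx[bad]] = True
    return eps, centric, absent
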