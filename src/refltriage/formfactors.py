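"""Atomic X-ray scattering factors (4-Gaussian parameterization).

Coefficients for H, C, N, O, P, S ship with the package; any other
element falls back to a constant equal to its electron count when one is
supplied, otherwise an error is raised.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = ["f0", "sum_f_squared", "known_elements", "electron_count"]


@lru_cache(maxsize=1)
def _table() -> dict:
    text = resources.files("refltriage.data").joinpath("form_factors_it92.json").read_text()
    raw = json.loads(text)
    raw.pop("comment", None)
    return {
        el: (np.array(v["a"]), np.array(v["b"]), float(v["c"]), int(v["z"]))
        for el, v in raw.items()
    }


def known_elements() -> tuple[str, ...]:
    return tuple(_table())


def electron_count(element: str) -> int:
    entry = _table().get(element)
    if entry is None:
        raise KeyError(f"no form factor for element {element!r}")
    return entry[3]


def f0(element: str, s2: np.ndarray, fallback_z: int | None = None) -> np.ndarray:
    """Scattering factor at s² = (sinθ/λ)² = 1/(4d²)  [Å⁻²]."""
    s2 = np.asarray(s2, dtype=float)
    entry = _table().get(element)
    if entry is None:
        if fallback_z is None:
            raise KeyError(f"no form factor for element {element!r}")
        return np.full_like(s2, float(fallback_z))
    a, b, c, _ = entry
    return (a[None, :] * np.exp(-b[None, :] * s2[..., None])).sum(axis=-1) + c


def sum_f_squared(composition: dict[str, float], s2: np.ndarray) -> np.ndarray:
    """Σ_j f_j²(s) for a composition given as {element: count}."""
    s2 = np.asarray(s2, dtype=float)
    total = np.zeros_like(s2)
    for el, count in composition.items():
        total += count * f0(el, s2) ** 2
    return total


#: a generic protein-like element mix (fractions of non-H atoms)
PROTEIN_FRACTIONS = {"C": 0.62, "N": 0.17, "O": 0.19, "S": 0.02}


def protein_composition(n_atoms: int) -> dict[str, float]:
    return {el: frac * n_atoms for el, frac in PROTEIN_FRACTIONS.items()}
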