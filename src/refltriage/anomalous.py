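"""Bijvoet-difference statistics and anomalous-signal measurability.

Measurability is the fraction of acentric Bijvoet pairs whose intensity
difference is statistically significant, |ΔI|/σ(ΔI) > cut; under pure
noise it equals the two-sided normal tail probability of the cut
(0.27% at 3σ), and it grows with the anomalous scattering strength f″.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .reflections import ReflectionSet, ShellScheme, bin_by_resolution

__all__ = ["BijvoetPairSet", "AnomalousReport", "bijvoet_pairs", "measurability"]


@dataclass
class BijvoetPairSet:
    data: pd.DataFrame  # h,k,l,d,Iplus,sigIplus,Iminus,sigIminus (acentric)
    n_singles: int      # acentric uniques with only one mate measured
    n_centric_excluded: int

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AnomalousReport:
    measurability: float
    mean_delta_over_sigma: float
    anomalous_completeness: float
    sigma_cut: float
    per_shell: pd.DataFrame
    n_pairs: int


def bijvoet_pairs(rset: ReflectionSet) -> BijvoetPairSet:
    """Extract matched acentric Bijvoet pairs from a merged anomalous set.

    Centric reflections are excluded: their true anomalous difference is
    zero by symmetry.
    """
    if not rset.anomalous:
        raise ValueError("no anomalous data in this reflection set")
    for col in ("Iplus", "sigIplus", "Iminus", "sigIminus"):
        if col not in rset.data.columns:
            raise ValueError("no anomalous data: Bijvoet columns missing")
    _, centric, absent = rset.classify()
    df = rset.data
    acentric = (~centric) & (~absent)
    n_centric = int((centric & ~absent).sum())
    both = acentric & df["Iplus"].notna().to_numpy() & df["Iminus"].notna().to_numpy()
    single = acentric & ~both & (df["Iplus"].notna() | df["Iminus"].notna()).to_numpy()
    out = df.loc[both, ["h", "k", "l", "d", "Iplus", "sigIplus", "Iminus", "sigIminus"]]
    return BijvoetPairSet(data=out.reset_index(drop=True),
                          n_singles=int(single.sum()),
                          n_centric_excluded=n_centric)


def measurability(pairs: BijvoetPairSet, sigma_cut: float = 3.0,
                  scheme: Optional[ShellScheme] = None) -> AnomalousReport:
    """Fraction of pairs with |I⁺−I⁻| / √(σ⁺²+σ⁻²) above ``sigma_cut``."""
    if not len(pairs):
        raise ValueError("empty Bijvoet pair set")
    df = pairs.data
    delta = df["Iplus"].to_numpy() - df["Iminus"].to_numpy()
    sig = np.sqrt(df["sigIplus"].to_numpy() ** 2 + df["sigIminus"].to_numpy() ** 2)
    ratio = np.abs(delta) / sig
    significant = ratio > sigma_cut
    d = df["d"].to_numpy()
    if scheme is None:
        order = np.sort(d)[::-1]
        n_shells = max(min(10, len(d) // 200), 1)
        edges = order[np.linspace(0, len(d) - 1, n_shells + 1).astype(int)]
        edges[0] *= 1.0001
        edges[-1] *= 0.9999
        edges = np.unique(edges)[::-1]
        scheme = ShellScheme(edges) if len(edges) > 1 else None
    rows = []
    if scheme is not None:
        shell = scheme.assign(d)
        for i in range(scheme.n_shells):
            m = shell == i
            rows.append(dict(
                shell=i, d_high=scheme.boundaries[i + 1], d_low=scheme.boundaries[i],
                n=int(m.sum()),
                measurability=float(significant[m].mean()) if m.sum() else np.nan,
                mean_delta_over_sigma=float(ratio[m].mean()) if m.sum() else np.nan,
            ))
    n_total = len(df) + pairs.n_singles
    return AnomalousReport(
        measurability=float(significant.mean()),
        mean_delta_over_sigma=float(ratio.mean()),
        anomalous_completeness=float(len(df) / n_total) if n_total else 0.0,
        sigma_cut=sigma_cut,
        per_shell=pd.DataFrame(rows),
        n_pairs=int(len(df)),
    )
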