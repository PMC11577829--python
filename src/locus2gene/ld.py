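"""Linkage-disequilibrium references used for clumping and simulation.

Two concrete providers are offered: :class:`LdPanel`, a dense per-chromosome
panel with an analytic block correlation structure (produced by the synthetic
generator), and :class:`PairwiseLd`, a sparse variant-pair table as read from
a tab-separated file. Both expose ``r(a, b)`` / ``covers(v)`` and can back the
greedy clumping routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LdPanel", "PairwiseLd", "read_ld_table", "write_ld_table"]


@dataclass
class LdPanel:
    """Ordered variant panel with pairwise allelic correlations.

    Parameters
    ----------
    chrom
        Chromosome label shared by all panel variants.
    variants
        Canonical variant ids (``chrom:pos:ref:alt``), in position order.
    positions
        1-based base-pair positions, parallel to ``variants``.
    maf
        Per-variant minor allele frequency, in ``(0, 0.5]``. The minor allele
        is the alternate/effect allele throughout the synthetic generator.
    corr
        Pairwise allelic correlation matrix (symmetric, unit diagonal, PSD).
    blocks
        Half-open ``(start, stop)`` index ranges of the independent LD blocks.
    rho
        Adjacent-variant correlation within a block (AR(1) decay).
    """

    chrom: str
    variants: list[str]
    positions: np.ndarray
    maf: np.ndarray
    corr: np.ndarray
    blocks: list[tuple[int, int]] = field(default_factory=list)
    rho: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        m = len(self.variants)
        if self.corr.shape != (m, m):
            raise ValueError("correlation matrix shape does not match variants")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not np.allclose(self.corr, self.corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        self._index = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def covers(self, variant: str) -> bool:
        return variant in self._index

    def index_of(self, variant: str) -> int:
        return self._index[variant]

    def r(self, a: str, b: str) -> float:
        return float(self.corr[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2


class PairwiseLd:
    """Sparse LD lookup from an explicit list of variant pairs.

    Unlisted pairs of covered variants are taken as uncorrelated (r = 0),
    mirroring the behaviour of reference-panel LD extracts that only store
    the upper triangle above some magnitude cutoff.
    """

    def __init__(self, pairs: dict[tuple[str, str], float]):
        self._r: dict[tuple[str, str], float] = {}
        self._covered: set[str] = set()
        for (a, b), r in pairs.items():
            self._r[(a, b)] = float(r)
            self._r[(b, a)] = float(r)
            self._covered.add(a)
            self._covered.add(b)

    def covers(self, variant: str) -> bool:
        return variant in self._covered

    def r(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r.get((a, b), 0.0)

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2


class MultiPanelLd:
    """LD lookup dispatching to one :class:`LdPanel` per chromosome.

    Variants on different chromosomes (or in different panels) are treated
    as uncorrelated.
    """

    def __init__(self, panels: dict[str, LdPanel]):
        self.panels = dict(panels)

    def covers(self, variant: str) -> bool:
        chrom = variant.split(":", 1)[0]
        panel = self.panels.get(chrom)
        return panel is not None and panel.covers(variant)

    def r(self, a: str, b: str) -> float:
        ca = a.split(":", 1)[0]
        cb = b.split(":", 1)[0]
        if ca != cb:
            return 0.0
        panel = self.panels.get(ca)
        if panel is None or not (panel.covers(a) and panel.covers(b)):
            return 0.0
        return panel.r(a, b)

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2


def read_ld_table(path) -> PairwiseLd:
    """Read a tab-separated VARIANT_A, VARIANT_B, R pair list."""
    df = pd.read_csv(path, sep="\t", dtype={"VARIANT_A": str, "VARIANT_B": str})
    for col in ("VARIANT_A", "VARIANT_B", "R"):
        if col not in df.columns:
            raise ValueError(f"LD table is missing mandatory column {col!r}")
    pairs = {
        (a, b): r for a, b, r in zip(df["VARIANT_A"], df["VARIANT_B"], df["R"])
    }
    return PairwiseLd(pairs)


def write_ld_table(panel: LdPanel, path, r_min: float = 1e-6) -> None:
    """Write the upper triangle of a panel's correlation matrix as TSV."""
    rows = []
    m = panel.n_variants
    for i in range(m):
        for j in range(i + 1, m):
            r = panel.corr[i, j]
            if abs(r) >= r_min:
                rows.append((panel.variants[i], panel.variants[j], r))
    pd.DataFrame(rows, columns=["VARIANT_A", "VARIANT_B", "R"]).to_csv(
        path, sep="\t", index=False
    )
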