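"""Windowed homeologous-SNP-density scan and SNP-deficit region calling.

An allotetraploid mapped to one progenitor's genome shows a roughly
constant density of heterozygous-like (homeologous) SNPs.  Tracts where
one subgenome's sequence has replaced the other's lose that signal, so
the scan tiles each chromosome with non-overlapping windows (10 kb by
default), counts homeologous SNPs among depth-eligible positions, tests
each eligible window for a deficit against the genome-wide density with
a one-sided test of proportions, adjusts with Benjamini-Hochberg, and
reports runs of at least ``min_run`` consecutive significant windows as
homeologous SNP deficit (HSD) regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import adjust_pvalues_bh, prop_test_less
from .variant_io import DepthTrack, SnpRecord

__all__ = [
    "ScanParams",
    "WindowStat",
    "HsdRegion",
    "compute_window_stats",
    "genome_snp_density",
    "test_window_deficit",
    "adjust_pvalues_bh",
    "call_hsd_regions",
    "scan",
    "windows_to_frame",
    "regions_to_frame",
]


@dataclass(frozen=True)
class ScanParams:
    """Scan thresholds.

    ``min_depth``/``max_depth_factor`` bound per-position depth for a
    position to count (floor 10 reads; ceiling twice the genome-wide mean
    over covered positions); windows need ``min_positions`` eligible
    positions to enter the test; ``min_run`` consecutive significant
    windows make a region; ``alpha`` applies to BH-adjusted p-values.
    """

    window_size: int = 10_000
    min_depth: int = 10
    max_depth_factor: float = 2.0
    min_positions: int = 8_000
    min_run: int = 5
    alpha: float = 0.01

    def __post_init__(self):
        if min(self.window_size, self.min_depth, self.min_positions, self.min_run) <= 0:
            raise ValueError("scan parameters must be positive")
        if self.max_depth_factor <= 0 or not 0 < self.alpha < 1:
            raise ValueError("scan parameters must be positive")
        if self.min_positions > self.window_size:
            raise ValueError("min_positions cannot exceed window_size")


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_eligible: int
    n_snps: int
    eligible_flag: bool
    p_value: float | None = None
    q_value: float | None = None

    @property
    def density(self) -> float:
        return self.n_snps / self.n_eligible if self.n_eligible else float("nan")


@dataclass(frozen=True)
class HsdRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    q_values: tuple[float, ...]

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000.0


def homeologous_snp_positions(snps: Iterable[SnpRecord]) -> dict[str, np.ndarray]:
    """Positions of heterozygous-like calls per chromosome.

    Homozygous-alternate records are fixed differences against the
    reference, not evidence of two homeologous copies, so they do not
    count toward homeologous SNP density.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in snps:
        if s.is_het:
            by_chrom.setdefault(s.chrom, []).append(s.pos)
    return {c: np.unique(np.array(p, dtype=np.int64)) for c, p in by_chrom.items()}


def compute_window_stats(
    snps: Iterable[SnpRecord] | dict[str, np.ndarray],
    depth: DepthTrack,
    params: ScanParams = ScanParams(),
) -> list[WindowStat]:
    """Tile chromosomes and count eligible positions / homeologous SNPs.

    A position is eligible when ``min_depth <= depth <= max_depth_factor *
    genome mean`` (mean over covered positions).  SNPs at ineligible
    positions do not count.  The final partial window is kept but flagged
    ineligible when it has fewer than ``min_positions`` eligible positions.
    """
    if not depth.depths:
        raise ValueError("empty depth track")
    snp_pos = (
        snps if isinstance(snps, dict) else homeologous_snp_positions(snps)
    )
    mean = depth.mean_depth(covered_only=True)
    depth_cap = params.max_depth_factor * mean
    out: list[WindowStat] = []
    for chrom in depth.chromosomes:
        arr = depth[chrom]
        ok = (arr >= params.min_depth) & (arr <= depth_cap)
        length = arr.size
        n_windows = (length + params.window_size - 1) // params.window_size
        edges = np.arange(n_windows + 1) * params.window_size
        edges[-1] = length
        n_eligible = np.add.reduceat(ok.astype(np.int64), edges[:-1])
        pos = snp_pos.get(chrom, np.empty(0, dtype=np.int64))
        pos = pos[(pos >= 0) & (pos < length)]
        pos = pos[ok[pos]]
        n_snps = np.bincount(pos // params.window_size, minlength=n_windows)
        for w in range(n_windows):
            ne = int(n_eligible[w])
            out.append(
                WindowStat(
                    chrom=chrom,
                    start=int(edges[w]),
                    end=int(edges[w + 1]),
                    n_eligible=ne,
                    n_snps=int(n_snps[w]),
                    eligible_flag=ne >= params.min_positions,
                )
            )
    return out


def genome_snp_density(windows: Sequence[WindowStat]) -> float:
    """Overall mean homeologous-SNP density over eligible positions of
    eligible windows — the null proportion for the deficit test."""
    n_elig = sum(w.n_eligible for w in windows if w.eligible_flag)
    n_snps = sum(w.n_snps for w in windows if w.eligible_flag)
    if n_elig == 0:
        raise ValueError("no eligible windows; cannot estimate genome-wide density")
    return n_snps / n_elig


def test_window_deficit(window: WindowStat, p0: float) -> float:
    """One-sided (deficit) test of the window's SNP proportion against p0."""
    if not window.eligible_flag:
        raise ValueError("ineligible window has no defined test")
    return prop_test_less(window.n_snps, window.n_eligible, p0)


def test_windows(
    windows: Sequence[WindowStat], p0: float | None = None
) -> tuple[list[WindowStat], float]:
    """Attach deficit p-values and BH q-values to eligible windows.

    Ineligible windows stay untested and are excluded from the
    multiple-testing universe.  Returns (windows, p0 used).
    """
    if p0 is None:
        p0 = genome_snp_density(windows)
    tested = [w for w in windows if w.eligible_flag]
    pvals = [test_window_deficit(w, p0) for w in tested]
    qvals = adjust_pvalues_bh(pvals)
    for w, p, q in zip(tested, pvals, qvals):
        w.p_value = float(p)
        w.q_value = float(q)
    return list(windows), p0


def call_hsd_regions(
    windows: Sequence[WindowStat], params: ScanParams = ScanParams()
) -> list[HsdRegion]:
    """Maximal runs of >= ``min_run`` consecutive significant windows.

    A window is significant when eligible and BH-adjusted p < alpha; an
    ineligible or non-significant window terminates a run.  Windows must
    already carry q-values (see :func:`test_windows`).
    """
    regions: list[HsdRegion] = []
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        ws = sorted(ws, key=lambda w: w.start)
        run: list[WindowStat] = []

        def _flush(run: list[WindowStat]):
            if len(run) >= params.min_run:
                regions.append(
                    HsdRegion(
                        chrom=chrom,
                        start=run[0].start,
                        end=run[-1].end,
                        n_windows=len(run),
                        q_values=tuple(w.q_value for w in run),
                    )
                )

        for w in ws:
            sig = (
                w.eligible_flag and w.q_value is not None and w.q_value < params.alpha
            )
            if sig:
                run.append(w)
            else:
                _flush(run)
                run = []
        _flush(run)
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def scan(
    snps: Iterable[SnpRecord] | dict[str, np.ndarray],
    depth: DepthTrack,
    params: ScanParams = ScanParams(),
) -> tuple[list[WindowStat], list[HsdRegion], float]:
    """Full scan: window stats, deficit tests with BH, region calls."""
    windows = compute_window_stats(snps, depth, params)
    windows, p0 = test_windows(windows)
    regions = call_hsd_regions(windows, params)
    return windows, regions, p0


def windows_to_frame(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_eligible": [w.n_eligible for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "density": [w.density for w in windows],
            "p_value": [w.p_value for w in windows],
            "q_value": [w.q_value for w in windows],
            "eligible": [w.eligible_flag for w in windows],
        }
    )


def regions_to_frame(regions: Sequence[HsdRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "size_kb": [r.size_kb for r in regions],
            "max_q": [max(r.q_values) if r.q_values else None for r in regions],
        }
    )
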