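"""Read-depth karyotyping: whole-chromosome copy number, diploidization,
and local copy number at an amplified locus.

Sequencing depth is summarized in 1 kb windows; per-chromosome mean depth,
normalized to the least-covered chromosome, gives a relative depth ratio
r_c per chromosome.  Copy numbers are called under two models — the least
covered chromosome carries one copy (base 1, the haploid expectation) or
two (base 2).  A strain whose ratios fit integers better under base 2 at
more than one aneuploid chromosome is flagged as diploidized (whole-genome
doubling).  The rDNA tandem array (chromosome XII) is excluded from the
chromosome means because its copy number varies independently of karyotype.
Local amplifications (e.g., a CUP1 tandem array on chromosome VIII) are
quantified as interval depth over the chromosome background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WINDOW_COLUMNS = ["chrom", "start", "end", "depth"]


@dataclass(frozen=True)
class KaryotypeCall:
    """Per-chromosome copy calls under the base-1 and base-2 models."""

    chrom_depths: dict[str, float]
    ratios: dict[str, float]  # normalized to least-covered chromosome
    copy_base1: dict[str, int]
    copy_base2: dict[str, int]
    diploidized: bool
    anomalous: bool = False


@dataclass(frozen=True)
class LocusCopyEstimate:
    chrom: str
    start: int
    end: int
    relative_depth: float  # interval depth / chromosome background depth
    copies: int  # integer copy estimate, scaled by the chromosome copy number


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _excluded(windows: pd.DataFrame, exclusions: Sequence[tuple[str, int, int]]) -> np.ndarray:
    mask = np.zeros(len(windows), dtype=bool)
    for chrom, start, end in exclusions:
        mask |= (
            (windows["chrom"] == chrom)
            & (windows["start"] < end)
            & (windows["end"] > start)
        ).to_numpy()
    return mask


def chromosome_depths(
    windows: pd.DataFrame,
    exclusions: Sequence[tuple[str, int, int]] = (),
) -> dict[str, float]:
    """Mean window depth per chromosome, skipping excluded intervals.

    ``windows`` has columns chrom, start, end (0-based half-open), depth.
    Windows overlapping any exclusion interval (the rDNA cluster, typically)
    are dropped before averaging.  A chromosome with every window excluded
    raises, since its copy number would be undefined.
    """
    keep = windows[~_excluded(windows, exclusions)]
    means = keep.groupby("chrom")["depth"].mean()
    lost = set(windows["chrom"].unique()) - set(means.index)
    if lost:
        raise ValueError(f"chromosome(s) fully excluded: {sorted(lost)}")
    return {str(c): float(d) for c, d in means.items()}


def call_karyotype(chrom_depths: Mapping[str, float]) -> KaryotypeCall:
    """Copy numbers from per-chromosome mean depths under both base models.

    Ratios are depths over the least-covered chromosome's depth; copy number
    is round(base x ratio) with .5 rounding up.  Base-1 copies are floored
    at 1 (a fully covered chromosome cannot have zero copies).
    """
    if not chrom_depths:
        raise ValueError("no chromosome depths")
    floor = min(chrom_depths.values())
    if floor <= 0:
        raise ValueError("least-covered chromosome has nonpositive depth")
    ratios = {c: d / floor for c, d in chrom_depths.items()}
    copy1 = {c: max(1, _round_half_up(r)) for c, r in ratios.items()}
    copy2 = {c: max(1, _round_half_up(2 * r)) for c, r in ratios.items()}
    call = KaryotypeCall(
        chrom_depths=dict(chrom_depths),
        ratios=ratios,
        copy_base1=copy1,
        copy_base2=copy2,
        diploidized=False,
    )
    return KaryotypeCall(
        chrom_depths=call.chrom_depths,
        ratios=call.ratios,
        copy_base1=call.copy_base1,
        copy_base2=call.copy_base2,
        diploidized=flag_diploidization(call),
    )


def flag_diploidization(call: KaryotypeCall) -> bool:
    """Whole-genome doubling flag.

    A chromosome supports diploidization when its depth ratio sits closer to
    an integer multiple of 1/2 than of 1 (i.e., the base-2 model fits it
    better) and its base-2 copy number is aneuploid (not 2).  More than one
    such chromosome flags the strain.
    """
    n_support = 0
    for c, r in call.ratios.items():
        resid1 = abs(r - round(r))
        resid2 = abs(2 * r - round(2 * r))
        if resid2 < resid1 and call.copy_base2[c] != 2:
            n_support += 1
    return n_support > 1


def locus_copy_number(
    windows: pd.DataFrame,
    interval: tuple[str, int, int],
    chromosome_copies: int = 1,
) -> LocusCopyEstimate:
    """Integer copy estimate for a locus from its depth over the background.

    Background is the mean window depth of the interval's chromosome outside
    the interval; the estimate is round(interval depth / background) scaled
    by the chromosome's own copy number.
    """
    chrom, start, end = interval
    on_chrom = windows[windows["chrom"] == chrom]
    if on_chrom.empty:
        raise ValueError(f"no windows on {chrom}")
    inside = (on_chrom["start"] < end) & (on_chrom["end"] > start)
    if not inside.any():
        raise ValueError("interval covers no windows")
    bg = on_chrom.loc[~inside, "depth"].mean()
    if not np.isfinite(bg) or bg <= 0:
        raise ValueError("background depth is zero or undefined")
    rel = float(on_chrom.loc[inside, "depth"].mean() / bg)
    copies = max(1, _round_half_up(rel) * chromosome_copies)
    return LocusCopyEstimate(chrom=chrom, start=start, end=end, relative_depth=rel, copies=copies)


def detect_step_boundaries(
    windows: pd.DataFrame,
    chrom: str,
    threshold: float = 2.0,
    k: int = 5,
) -> list[tuple[int, float]]:
    """Step-like depth changepoints along one chromosome.

    Scans each window junction and compares the mean depth of the k windows
    on either side; junctions where the ratio (larger/smaller) exceeds
    ``threshold`` are reported, keeping only the locally strongest junction
    within each run of consecutive detections.  Returns (position, ratio of
    right mean to left mean) pairs; a ratio > 1 is a step up.
    """
    sub = windows[windows["chrom"] == chrom].sort_values("start").reset_index(drop=True)
    if len(sub) < 10:
        raise ValueError("need >= 10 windows for a step scan")
    depth = sub["depth"].to_numpy(dtype=float)
    hits = []  # (junction index, signed ratio, fold)
    for j in range(1, len(depth)):
        left = depth[max(0, j - k) : j].mean()
        right = depth[j : j + k].mean()
        lo, hi = min(left, right), max(left, right)
        if lo <= 0:
            fold = np.inf if hi > 0 else 1.0
        else:
            fold = hi / lo
        if fold > threshold:
            hits.append((j, right / max(left, 1e-12), fold))
    # collapse runs of adjacent junctions to the strongest one
    out: list[tuple[int, float]] = []
    run: list[tuple[int, float, float]] = []
    for h in hits:
        if run and h[0] > run[-1][0] + 1:
            best = max(run, key=lambda t: t[2])
            out.append((int(sub.loc[best[0], "start"]), best[1]))
            run = []
        run.append(h)
    if run:
        best = max(run, key=lambda t: t[2])
        out.append((int(sub.loc[best[0], "start"]), best[1]))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_coverage(path: str) -> pd.DataFrame:
    """Read a bedGraph/TSV coverage track (chrom, start, end, depth)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="t")
    if df.shape[1] < 4:
        raise ValueError("coverage track needs 4 columns: chrom start end depth")
    df = df.iloc[:, :4]
    df.columns = WINDOW_COLUMNS
    return df.astype({"start": int, "end": int, "depth": float})


def read_exclusions(path: str) -> list[tuple[str, int, int]]:
    """Read exclusion intervals from a 3-column BED."""
    df = pd.read_csv(path, sep="\t", header=None).iloc[:, :3]
    return [(str(r[0]), int(r[1]), int(r[2])) for r in df.itertuples(index=False)]


def write_karyotype(call: KaryotypeCall, strain: str, tsv_path: str, json_path: str | None = None) -> None:
    rows = [
        {
            "strain": strain,
            "chrom": c,
            "ratio": call.ratios[c],
            "copy_base1": call.copy_base1[c],
            "copy_base2": call.copy_base2[c],
        }
        for c in call.ratios
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"strain": strain, "diploidized": call.diploidized, "anomalous": call.anomalous}, fh)
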