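"""Fixed-width genomic binning of copy status and arm-level summaries.

Chromosomes are tiled with non-overlapping 100 kb bins (half-open,
0-based internally; the final partial bin runs to the chromosome end).
Each bin takes the ploidy-relative status of the overlapping segment with
the greatest overlap (ties broken toward the higher total copy number);
bins with no overlapping segment are ``no_data`` and are excluded from
group-frequency denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CopySegment, GenomeLayout
from .mutation_landscape import HOMDEL_MAX_CN

DEFAULT_BIN_WIDTH = 100_000

AMPLIFIED, NEUTRAL, DELETED, NO_DATA = "amplified", "neutral", "deleted", "no_data"


@dataclass
class BinTrack:
    """Per-sample copy status over a fixed bin tiling."""

    bins: pd.DataFrame        # columns chrom, start, end (0-based half-open)
    status: pd.DataFrame      # index = bin number, columns = samples, str
    width: int = DEFAULT_BIN_WIDTH


def make_bins(layout: GenomeLayout, width: int = DEFAULT_BIN_WIDTH,
              chroms: Sequence[str] | None = None) -> pd.DataFrame:
    """Half-open [0, w), [w, 2w), ... tiling with a final partial bin."""
    if width <= 0:
        raise ValueError("width must be > 0")
    rows = []
    for chrom in (chroms or layout.chrom_lengths):
        length = layout.chrom_lengths[chrom]
        start = 0
        while start < length:
            rows.append({"chrom": chrom, "start": start,
                         "end": min(start + width, length)})
            start += width
    return pd.DataFrame(rows)


def _segment_status(total_cn: float, ploidy: float) -> str:
    if total_cn >= 2.0 * ploidy:
        return AMPLIFIED
    if total_cn < HOMDEL_MAX_CN:
        return DELETED
    return NEUTRAL


def map_status_to_bins(segments: Sequence[CopySegment], ploidy: float,
                       bins: pd.DataFrame) -> pd.Series:
    """Copy status per bin for one sample.

    Segment coordinates are 1-based inclusive; bins 0-based half-open.  A
    bin covered by several segments takes the status of the segment with
    the greatest overlap, ties resolved toward the higher total_cn.
    """
    statuses = np.full(len(bins), NO_DATA, dtype=object)
    best_overlap = np.zeros(len(bins))
    best_cn = np.full(len(bins), -np.inf)
    bstart = bins["start"].to_numpy()
    bend = bins["end"].to_numpy()
    bchrom = bins["chrom"].to_numpy()
    for seg in segments:
        s0, s1 = seg.start - 1, seg.end  # to 0-based half-open
        idx = np.nonzero((bchrom == seg.chrom) & (bstart < s1) & (bend > s0))[0]
        if idx.size == 0:
            continue
        ov = np.minimum(bend[idx], s1) - np.maximum(bstart[idx], s0)
        take = (ov > best_overlap[idx]) | (
            (ov == best_overlap[idx]) & (seg.total_cn > best_cn[idx]))
        sel = idx[take]
        best_overlap[sel] = ov[take]
        best_cn[sel] = seg.total_cn
        statuses[sel] = _segment_status(seg.total_cn, ploidy)
    return pd.Series(statuses, index=bins.index)


def build_tracks(segments: Sequence[CopySegment],
                 ploidies: Mapping[str, float],
                 bins: pd.DataFrame) -> BinTrack:
    by_sample: dict[str, list[CopySegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    cols = {}
    for sid, segs in sorted(by_sample.items()):
        if sid not in ploidies:
            raise ValueError(f"missing ploidy for {sid}")
        cols[sid] = map_status_to_bins(segs, ploidies[sid], bins)
    return BinTrack(bins=bins, status=pd.DataFrame(cols),
                    width=int((bins["end"] - bins["start"]).max()))


def group_bin_frequency(track: BinTrack,
                        groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Per-bin, per-group fraction of samples amplified / deleted, over
    samples with data in the bin.  Long-format output."""
    rows = []
    for name, ids in groups.items():
        ids = [i for i in ids if i in track.status.columns]
        if not ids:
            raise ValueError(f"group {name!r} has no samples with tracks")
        sub = track.status[ids]
        informative = (sub != NO_DATA).sum(axis=1)
        amp = (sub == AMPLIFIED).sum(axis=1)
        dele = (sub == DELETED).sum(axis=1)
        with np.errstate(invalid="ignore"):
            f_amp = np.where(informative > 0, amp / informative, np.nan)
            f_del = np.where(informative > 0, dele / informative, np.nan)
        for i in track.bins.index:
            rows.append({
                "chrom": track.bins.at[i, "chrom"],
                "start": int(track.bins.at[i, "start"]),
                "end": int(track.bins.at[i, "end"]),
                "group": name, "n_informative": int(informative[i]),
                "frac_amplified": float(f_amp[i]),
                "frac_deleted": float(f_del[i]),
            })
    return pd.DataFrame(rows)


def arm_amplified_fraction(track: BinTrack, layout: GenomeLayout, arm: str,
                           groups: Mapping[str, Sequence[str]] | None = None,
                           threshold: float = 0.7) -> pd.DataFrame:
    """Per-sample fraction of informative arm bins amplified, plus the
    sample-level arm call (fraction >= threshold) and per-group carrier
    frequency.

    The threshold is a reporting convention (the underlying event is a
    broad, near-whole-arm gain); 0.7 of informative bins is the default.
    """
    chrom, a_start, a_end = layout.arm_interval(arm)
    sel = (track.bins["chrom"] == chrom) \
        & (track.bins["start"] < a_end) & (track.bins["end"] > a_start - 1)
    sub = track.status.loc[sel.to_numpy()]
    rows = []
    informative = (sub != NO_DATA).sum(axis=0)
    amplified = (sub == AMPLIFIED).sum(axis=0)
    frac = amplified / informative.replace(0, np.nan)
    for sid in sub.columns:
        f = frac[sid]
        rows.append({"arm": arm, "sample_id": sid,
                     "amplified_bin_fraction": float(f) if pd.notna(f) else np.nan,
                     "arm_amplified": bool(pd.notna(f) and f >= threshold)})
    per_sample = pd.DataFrame(rows)
    if groups is None:
        return per_sample
    grows = []
    for name, ids in groups.items():
        ids = [i for i in ids if i in set(per_sample["sample_id"])]
        sub2 = per_sample[per_sample["sample_id"].isin(ids)]
        grows.append({"arm": arm, "group": name, "n": len(sub2),
                      "n_arm_amplified": int(sub2["arm_amplified"].sum()),
                      "frac_arm_amplified": float(sub2["arm_amplified"].mean())
                      if len(sub2) else np.nan})
    per_sample = per_sample.merge(pd.DataFrame(grows), on="arm", how="left")
    return per_sample


def arm_group_summary(track: BinTrack, layout: GenomeLayout, arm: str,
                      groups: Mapping[str, Sequence[str]],
                      threshold: float = 0.7) -> pd.DataFrame:
    """Group-level arm-amplification frequencies only."""
    per_sample = arm_amplified_fraction(track, layout, arm, threshold=threshold)
    rows = []
    for name, ids in groups.items():
        sub = per_sample[per_sample["sample_id"].isin(list(ids))]
        rows.append({"arm": arm, "group": name, "n": len(sub),
                     "n_arm_amplified": int(sub["arm_amplified"].sum()),
                     "frac_arm_amplified": float(sub["arm_amplified"].mean())
                     if len(sub) else np.nan})
    return pd.DataFrame(rows)
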