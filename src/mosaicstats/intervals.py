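"""Genomic interval tracks with explicit coordinate conventions.

Internally every interval is 1-based inclusive ``[start, end]`` (VCF-style,
because variant positions dominate the data model).  BED files are converted
on read and write (0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class IntervalTrack:
    """A named set of genomic intervals with optional per-interval scores.

    Parameters
    ----------
    name : str
        Track label (e.g. ``"tfbs"``, ``"dhs"``).
    frame : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end`` (1-based inclusive) and
        optionally ``score``.
    provenance : str
        Free-text note on where the intervals came from.
    """

    name: str
    frame: pd.DataFrame
    provenance: str = ""
    merged: bool = field(default=False)

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"track frame needs columns {req}")
        if (self.frame["start"] > self.frame["end"]).any():
            raise ValueError("interval with start > end")
        self.frame = (
            self.frame.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_scores(self) -> bool:
        return "score" in self.frame.columns

    @property
    def scores(self) -> np.ndarray:
        if not self.has_scores:
            raise ValueError(f"track {self.name!r} carries no scores")
        return self.frame["score"].to_numpy(dtype=float)

    def midpoints(self) -> pd.DataFrame:
        """Interval midpoints, ``floor((start+end)/2)`` per interval."""
        mids = (self.frame["start"] + self.frame["end"]) // 2
        return pd.DataFrame({"chrom": self.frame["chrom"], "pos": mids})

    # -- set operations ----------------------------------------------------

    def merge(self) -> "IntervalTrack":
        """Union of intervals per chromosome (scores dropped)."""
        rows = []
        for chrom, sub in self.frame.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e + 1:  # adjacent 1-based intervals also merge
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return IntervalTrack(self.name, out, self.provenance, merged=True)

    def total_span(self) -> int:
        """Number of bases covered by the union of the intervals."""
        m = self if self.merged else self.merge()
        return int((m.frame["end"] - m.frame["start"] + 1).sum())

    def contains(self, chrom: np.ndarray | str, pos: np.ndarray) -> np.ndarray:
        """Boolean membership for 1-based positions (inclusive at both ends)."""
        pos = np.asarray(pos, dtype=np.int64)
        if isinstance(chrom, str):
            chrom = np.full(pos.shape, chrom, dtype=object)
        chrom = np.asarray(chrom, dtype=object)
        out = np.zeros(pos.shape, dtype=bool)
        m = self if self.merged else self.merge()
        for c, sub in m.frame.groupby("chrom", sort=False):
            sel = chrom == c
            if not sel.any():
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            idx = np.searchsorted(starts, pos[sel], side="right") - 1
            ok = idx >= 0
            ok[ok] = pos[sel][ok] <= ends[idx[ok]]
            out[sel] = ok
        return out

    def mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean per-base coverage mask for one contig (index 0 = pos 1)."""
        m = self if self.merged else self.merge()
        out = np.zeros(length, dtype=bool)
        sub = m.frame[m.frame["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            out[max(s - 1, 0): min(e, length)] = True
        return out

    # -- IO ----------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """Write BED (0-based half-open); scores go to column 5."""
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                fields = [str(row.chrom), str(row.start - 1), str(row.end)]
                if self.has_scores:
                    fields += [".", f"{row.score:g}"]
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "IntervalTrack":
        """Read BED3/BED5 into 1-based inclusive coordinates."""
        path = Path(path)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
                score = float(parts[4]) if len(parts) >= 5 else None
                rows.append((chrom, start, end, score))
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        if frame["score"].isna().all():
            frame = frame.drop(columns="score")
        return cls(name or path.stem, frame, provenance=str(path))


def promoter_track(tss: pd.DataFrame, window: int = 2500, name: str = "promoters",
                   genome_length: int | None = None) -> IntervalTrack:
    """Promoters as the ``window`` bases upstream of each TSS.

    ``tss`` needs columns ``chrom``, ``pos`` and optionally ``strand``
    (default ``+``).  On the plus strand a TSS at position t yields
    ``[t - window, t - 1]``; on the minus strand ``[t + 1, t + window]``.
    Intervals are clipped to ``[1, genome_length]`` when a length is given.
    """
    strand = tss["strand"] if "strand" in tss.columns else pd.Series("+", index=tss.index)
    plus = strand == "+"
    start = np.where(plus, tss["pos"] - window, tss["pos"] + 1)
    end = np.where(plus, tss["pos"] - 1, tss["pos"] + window)
    frame = pd.DataFrame({"chrom": tss["chrom"], "start": start, "end": end})
    frame["start"] = frame["start"].clip(lower=1)
    if genome_length is not None:
        frame["end"] = frame["end"].clip(upper=genome_length)
    frame = frame[frame["start"] <= frame["end"]]
    return IntervalTrack(name, frame.reset_index(drop=True))
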