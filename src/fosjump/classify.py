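"""Classify aligned Fosmid end pairs into correct jumps and chimaera classes.

Definitions follow the standard jumping-library conventions:

* unambiguously mapped pairs: both ends aligned with mapping quality > 0;
* duplicates: pairs whose forward/reverse 5' start sites are identical on
  both sides;
* correct jumps: ends face each other (convergent) 20-50 kb apart;
* chimaeric jumps: unexpected orientation (divergent/"inverted" or tandem)
  or unexpected spacing (outside the window; spans > 100 kb are additionally
  flagged) or ends on different contigs.

Span is the outer-to-outer distance between the pair's outermost reference
coordinates (a proxy for the clone insert length).  The reported chimaera
rate counts every non-correct unique pair ("results" convention); a stricter
convention counting only >100-kb/inter-contig spacing plus orientation
anomalies ("methods" convention) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = (20_000, 50_000)
DEFAULT_LONG_CUT = 100_000

LABELS = ("correct", "chim_orientation", "chim_short", "chim_long", "chim_intercontig")


@dataclass(frozen=True)
class AlignedEnd:
    read_id: str  # base id, without the /1 or /2 suffix
    side: int  # 1 or 2
    contig: str
    start: int  # 0-based half-open on the reference
    end: int
    strand: str
    mapq: int
    score: int = 0
    supplementary: bool = False

    @property
    def five_prime(self) -> int:
        """5' mapping coordinate (start site of the sequencing read)."""
        return self.start if self.strand == "+" else self.end

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")


@dataclass
class JumpRecord:
    read_id: str
    left: AlignedEnd  # canonical order: (contig, start) ascending
    right: AlignedEnd
    span: int | None  # outermost distance; None when inter-contig
    orientation: str  # convergent | divergent | tandem | intercontig
    label: str
    over_long_cut: bool = False
    duplicate: bool = False


def load_alignments(
    path: str,
    fmt: str | None = None,
    min_mapq: int = 0,
    drop_supplementary: bool = True,
) -> dict[tuple[str, int], AlignedEnd]:
    """Load SAM/BAM or PAF alignments keyed by (read id, side).

    Read names must carry ``/1``/``/2`` side suffixes.  Secondary alignments
    are skipped; supplementary ones are skipped when ``drop_supplementary``.
    Per (read, side), the best alignment wins: higher mapq, then higher
    score, then lexicographic (contig, position) — deterministic.
    """
    if fmt is None:
        fmt = "paf" if path.endswith(".paf") else "sam"
    ends: list[AlignedEnd] = []
    if fmt == "sam":
        import pysam

        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                if drop_supplementary and rec.is_supplementary:
                    continue
                rid, side = _split_side(rec.query_name)
                score = rec.get_tag("AS") if rec.has_tag("AS") else 0
                ends.append(
                    AlignedEnd(
                        read_id=rid,
                        side=side,
                        contig=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                        score=int(score),
                        supplementary=rec.is_supplementary,
                    )
                )
    elif fmt == "paf":
        with open(path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if len(f) < 12:
                    raise ValueError("malformed PAF line")
                rid, side = _split_side(f[0])
                ends.append(
                    AlignedEnd(
                        read_id=rid,
                        side=side,
                        contig=f[5],
                        start=int(f[7]),
                        end=int(f[8]),
                        strand=f[4],
                        mapq=int(f[11]),
                        score=int(f[9]),
                    )
                )
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")

    best: dict[tuple[str, int], AlignedEnd] = {}
    for e in ends:
        if e.mapq < min_mapq:
            continue
        key = (e.read_id, e.side)
        cur = best.get(key)
        if cur is None or _rank(e) > _rank(cur):
            best[key] = e
    return best


def _split_side(name: str) -> tuple[str, int]:
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    raise ValueError(f"read name {name!r} lacks a /1 or /2 side suffix")


def _rank(e: AlignedEnd) -> tuple:
    # higher is better; contig/pos descending-lexicographic makes min win
    return (e.mapq, e.score, tuple(-ord(c) for c in e.contig), -e.start)


def classify_pair(
    left: AlignedEnd,
    right: AlignedEnd,
    spacing_window: tuple[int, int] = DEFAULT_WINDOW,
    long_cut: int = DEFAULT_LONG_CUT,
) -> JumpRecord:
    """Label one unambiguous pair.

    Inter-contig -> chim_intercontig; non-convergent orientation ->
    chim_orientation (divergent or tandem); convergent with span inside the
    window -> correct; below the window -> chim_short; above -> chim_long
    (flagged additionally when the span exceeds ``long_cut``).
    """
    if left.contig != right.contig:
        a, b = sorted((left, right), key=lambda e: e.contig)
        return JumpRecord(left.read_id, a, b, None, "intercontig", "chim_intercontig")
    a, b = sorted((left, right), key=lambda e: (e.start, e.end))
    span = max(a.end, b.end) - min(a.start, b.start)
    if a.strand == b.strand:
        orientation = "tandem"
    elif a.strand == "+":
        orientation = "convergent"
    else:
        orientation = "divergent"
    if orientation != "convergent":
        label = "chim_orientation"
    elif span < spacing_window[0]:
        label = "chim_short"
    elif span > spacing_window[1]:
        label = "chim_long"
    else:
        label = "correct"
    return JumpRecord(left.read_id, a, b, span, orientation, label, over_long_cut=span > long_cut)


def pair_and_classify(
    ends: dict[tuple[str, int], AlignedEnd],
    spacing_window: tuple[int, int] = DEFAULT_WINDOW,
    long_cut: int = DEFAULT_LONG_CUT,
    min_mapq: int = 1,
) -> tuple[list[JumpRecord], int]:
    """Pair up /1 and /2 ends and classify the unambiguous pairs.

    Returns (jumps, n_not_unambiguous): pairs with a missing side or an end
    below ``min_mapq`` (default: mapping quality > 0) are not classified.
    """
    read_ids = sorted({rid for rid, _ in ends})
    jumps: list[JumpRecord] = []
    ambiguous = 0
    for rid in read_ids:
        e1, e2 = ends.get((rid, 1)), ends.get((rid, 2))
        if e1 is None and e2 is None:
            continue
        if e1 is None or e2 is None or e1.mapq < min_mapq or e2.mapq < min_mapq:
            ambiguous += 1
            continue
        jumps.append(classify_pair(e1, e2, spacing_window, long_cut))
    return jumps, ambiguous


def deduplicate(jumps: list[JumpRecord]) -> tuple[list[JumpRecord], int]:
    """Collapse pairs with identical 5' start sites on both sides.

    The first pair in read-id order represents each group; removed pairs
    get their duplicate flag set.  Returns (unique jumps, duplicate count).
    """
    seen: dict[tuple, JumpRecord] = {}
    unique: list[JumpRecord] = []
    ndup = 0
    for j in sorted(jumps, key=lambda x: x.read_id):
        key = (
            j.left.contig,
            j.left.five_prime,
            j.left.strand,
            j.right.contig,
            j.right.five_prime,
            j.right.strand,
        )
        if key in seen:
            j.duplicate = True
            ndup += 1
        else:
            seen[key] = j
            unique.append(j)
    return unique, ndup


@dataclass
class JumpSummary:
    n_pairs: int  # classified (unambiguous) pairs
    n_not_unambiguous: int
    n_unique: int
    n_duplicates: int
    counts: dict[str, int] = field(default_factory=dict)  # labels over unique pairs
    correct_fraction: float = 0.0  # of unique unambiguous pairs
    chimaera_rate: float = 0.0  # non-correct fraction of unique pairs
    span_mean: float = float("nan")
    span_sd: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "pairs_unambiguous": self.n_pairs,
            "pairs_not_unambiguous": self.n_not_unambiguous,
            "unambiguous_fraction": self.n_pairs / max(self.n_pairs + self.n_not_unambiguous, 1),
            "unique_pairs": self.n_unique,
            "duplicates": self.n_duplicates,
            "correct_fraction_unique": self.correct_fraction,
            "chimaera_rate": self.chimaera_rate,
            "span_mean": self.span_mean,
            "span_sd": self.span_sd,
        }
        for k in LABELS:
            d[f"count_{k}"] = self.counts.get(k, 0)
        return d


def summarize(
    jumps: list[JumpRecord],
    n_not_unambiguous: int = 0,
    convention: str = "results",
) -> JumpSummary:
    """Aggregate classified jumps into the library summary.

    The chimaera rate is computed over unique unambiguous pairs.  Under the
    default "results" convention every non-correct unique pair is chimaeric;
    under "methods" only orientation anomalies, inter-contig pairs and spans
    beyond the long cut count (spacing merely outside 20-50 kb does not).
    """
    if not jumps:
        raise ValueError("no classified jumps")
    unique = [j for j in jumps if not j.duplicate]
    counts: dict[str, int] = {}
    for j in unique:
        counts[j.label] = counts.get(j.label, 0) + 1
    n_unique = len(unique)
    correct = counts.get("correct", 0)
    if convention == "results":
        chim = n_unique - correct
    elif convention == "methods":
        chim = sum(
            1
            for j in unique
            if j.label in ("chim_orientation", "chim_intercontig") or (j.label == "chim_long" and j.over_long_cut)
        )
    else:
        raise ValueError(f"unknown chimaera convention {convention!r}")
    spans = [j.span for j in unique if j.label == "correct"]
    return JumpSummary(
        n_pairs=len(jumps),
        n_not_unambiguous=n_not_unambiguous,
        n_unique=n_unique,
        n_duplicates=len(jumps) - n_unique,
        counts=counts,
        correct_fraction=correct / n_unique,
        chimaera_rate=chim / n_unique,
        span_mean=float(np.mean(spans)) if spans else float("nan"),
        span_sd=float(np.std(spans, ddof=1)) if len(spans) > 1 else float("nan"),
    )


def span_histogram(jumps: list[JumpRecord], bin_size: int = 1000) -> pd.DataFrame:
    """Percentage of unique same-contig pairs per span bin (1-kb default)."""
    spans = [j.span for j in jumps if not j.duplicate and j.span is not None]
    if not spans:
        return pd.DataFrame(columns=["bin_start", "count", "percent"])
    spans = np.asarray(spans)
    bins = spans // bin_size
    idx, counts = np.unique(bins, return_counts=True)
    return pd.DataFrame(
        {
            "bin_start": idx * bin_size,
            "count": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )


def jumps_table(jumps: list[JumpRecord]) -> pd.DataFrame:
    """One row per classified pair (for TSV output and the SV caller)."""
    rows = []
    for j in jumps:
        rows.append(
            {
                "read_id": j.read_id,
                "contig1": j.left.contig,
                "start1": j.left.start,
                "end1": j.left.end,
                "strand1": j.left.strand,
                "contig2": j.right.contig,
                "start2": j.right.start,
                "end2": j.right.end,
                "strand2": j.right.strand,
                "span": j.span if j.span is not None else -1,
                "orientation": j.orientation,
                "label": j.label,
                "over_long_cut": int(j.over_long_cut),
                "duplicate": int(j.duplicate),
            }
        )
    return pd.DataFrame(rows)


def jumps_from_table(df: pd.DataFrame) -> list[JumpRecord]:
    out = []
    for r in df.itertuples(index=False):
        left = AlignedEnd(r.read_id, 1, r.contig1, r.start1, r.end1, r.strand1, 60)
        right = AlignedEnd(r.read_id, 2, r.contig2, r.start2, r.end2, r.strand2, 60)
        j = JumpRecord(
            r.read_id,
            left,
            right,
            None if r.span < 0 else int(r.span),
            r.orientation,
            r.label,
            bool(r.over_long_cut),
            bool(r.duplicate),
        )
        out.append(j)
    return out
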