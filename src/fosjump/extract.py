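"""Recover Fosmid end sequences (FES-1/FES-2) from long reads.

A released paired-end molecule reads [VES1 | FES-1 | Amp | FES-2 | VES2]:
the two vector end stubs (348 bp and 300 bp) and the 1218-bp ampicillin
resistance tag are located in each read by a seeded local aligner (exact
13-mer seeds clustered by diagonal, candidate windows scored with edlib
infix alignment), the layout is resolved on either strand, and the genomic
segments between the tags are emitted:

* FES-1 is the VES1-adjacent end, written 5'->3' from the left cloning
  junction into the insert (output id suffix ``/1``);
* FES-2 is the VES2-adjacent end, written 5'->3' from the right cloning
  junction into the insert, i.e. reverse-complemented relative to the
  molecule (suffix ``/2``) — so a correct pair aligns convergently.

The VES stubs themselves are excluded from the reported FES sequences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from ._seq import revcomp

DEFAULT_MIN_IDENTITY = 0.75
DEFAULT_MIN_COVER = 0.5
DEFAULT_MIN_END_LEN = 50
_SEED_K = 13
_MIN_SEEDS = 3


@dataclass
class TagHit:
    tag: str  # VES1 | VES2 | AmpTag
    start: int  # on the read, 0-based half-open
    end: int
    strand: str
    identity: float
    score: int  # number of supporting seeds


@dataclass
class EndPair:
    read_id: str
    fes1: str
    fes1_interval: tuple[int, int]
    fes2: str
    fes2_interval: tuple[int, int]
    orientation_resolved: bool = True

    @property
    def lengths(self) -> tuple[int, int]:
        return len(self.fes1), len(self.fes2)


@dataclass
class SingleEnd:
    read_id: str
    side: int  # 1 or 2
    seq: str
    interval: tuple[int, int]


@dataclass
class Rejection:
    read_id: str
    reason: str  # no_amp | ambiguous | no_ves | layout


def _seed_clusters(read: str, tag: str, strand: str) -> list[tuple[int, int, int]]:
    """Candidate (window_start, window_end, n_seeds) via diagonal clustering."""
    k = _SEED_K
    if len(tag) < k or len(read) < k:
        return []
    tag_index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(tag) - k + 1):
        tag_index[tag[i : i + k]].append(i)
    diags: dict[int, int] = defaultdict(int)
    bucket = max(16, len(tag) // 8)
    for j in range(len(read) - k + 1):
        for i in tag_index.get(read[j : j + k], ()):
            diags[(j - i) // bucket] += 1
    out = []
    used = set()
    for d, n in sorted(diags.items(), key=lambda x: -x[1]):
        if n < _MIN_SEEDS or d in used:
            continue
        used.update((d - 1, d, d + 1))
        est = d * bucket + bucket // 2
        margin = max(30, len(tag) // 5)
        w0 = max(0, est - margin)
        w1 = min(len(read), est + len(tag) + margin)
        # merge votes from adjacent buckets
        n_total = diags.get(d - 1, 0) + n + diags.get(d + 1, 0)
        out.append((w0, w1, n_total))
    return out


def find_tags(
    read: str,
    tag_sequences: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_cover: float = DEFAULT_MIN_COVER,
) -> list[TagHit]:
    """Locate vector tags on both strands of a read.

    Each candidate window (from seed clustering) is scored by edlib infix
    alignment of the full tag; identity is 1 - edits/tag_length, so missing
    tag coverage counts against identity as well.  Overlapping same-tag hits
    are merged keeping the best.  Hits are sorted by score (seed support).
    """
    if not read:
        raise ValueError("empty read")
    hits: list[TagHit] = []
    for tag_name, tag in tag_sequences.items():
        for strand in "+-":
            t = tag if strand == "+" else revcomp(tag)
            for w0, w1, n_seeds in _seed_clusters(read, t, strand):
                window = read[w0:w1]
                res = edlib.align(t, window, mode="HW", task="locations")
                d = res["editDistance"]
                if d < 0 or not res["locations"]:
                    continue
                identity = 1.0 - d / len(tag)
                loc = res["locations"][0]
                start, end = w0 + loc[0], w0 + loc[1] + 1
                cover = (end - start) / len(tag)
                if identity < min_identity or cover < min_cover:
                    continue
                hits.append(TagHit(tag=tag_name, start=start, end=end, strand=strand, identity=identity, score=n_seeds))
    # merge overlapping hits of the same tag, keep best identity
    hits.sort(key=lambda h: (h.tag, h.start))
    merged: list[TagHit] = []
    for h in hits:
        if merged and merged[-1].tag == h.tag and h.start < merged[-1].end:
            if (h.identity, h.score) > (merged[-1].identity, merged[-1].score):
                merged[-1] = h
        else:
            merged.append(h)
    merged.sort(key=lambda h: -h.score)
    return merged


def extract_end_pair(read_id: str, read: str, hits: list[TagHit]) -> EndPair | SingleEnd | Rejection:
    """Resolve the tag layout of one read into a pair, a single end, or a rejection.

    Accepted layouts (forward or reverse-complement):
    ``VES1 - genomic - Amp - genomic - VES2`` -> pair;
    ``VES1 - genomic - Amp`` or ``Amp - genomic - VES2`` -> single end.
    Two Amp hits are ambiguous (no splitting rule is applied).
    """
    amp = [h for h in hits if h.tag == "AmpTag"]
    ves1 = [h for h in hits if h.tag == "VES1"]
    ves2 = [h for h in hits if h.tag == "VES2"]
    if len(amp) > 1:
        return Rejection(read_id, "ambiguous")
    if not amp:
        return Rejection(read_id, "no_amp")
    a = amp[0]
    v1 = max(ves1, key=lambda h: h.identity) if ves1 else None
    v2 = max(ves2, key=lambda h: h.identity) if ves2 else None
    if v1 is None and v2 is None:
        return Rejection(read_id, "no_ves")

    if v1 is not None and v2 is not None:
        # forward: VES1 < Amp < VES2 ; reverse: VES2 < Amp < VES1
        if v1.end <= a.start and a.end <= v2.start:
            fes1 = read[v1.end : a.start]
            fes2 = revcomp(read[a.end : v2.start])
            return EndPair(read_id, fes1, (v1.end, a.start), fes2, (a.end, v2.start))
        if v2.end <= a.start and a.end <= v1.start:
            fes1 = revcomp(read[a.end : v1.start])
            fes2 = read[v2.end : a.start]
            return EndPair(read_id, fes1, (a.end, v1.start), fes2, (v2.end, a.start))
    # single-end layouts; a spurious partial second VES (released vector
    # debris can carry one) falls through to the consistent side
    if v1 is not None:
        if v1.end <= a.start:
            return SingleEnd(read_id, 1, read[v1.end : a.start], (v1.end, a.start))
        if a.end <= v1.start:
            return SingleEnd(read_id, 1, revcomp(read[a.end : v1.start]), (a.end, v1.start))
    if v2 is not None:
        if a.end <= v2.start:
            return SingleEnd(read_id, 2, revcomp(read[a.end : v2.start]), (a.end, v2.start))
        if v2.end <= a.start:
            return SingleEnd(read_id, 2, read[v2.end : a.start], (v2.end, a.start))
    return Rejection(read_id, "layout")


def filter_ends(
    results: list[EndPair | SingleEnd], min_len: int = DEFAULT_MIN_END_LEN
) -> tuple[list[EndPair], list[SingleEnd]]:
    """Drop ends shorter than ``min_len`` (a 50-bp end is kept: >= is kept).

    A pair with exactly one surviving end degrades to a single end.
    """
    pairs: list[EndPair] = []
    singles: list[SingleEnd] = []
    for r in results:
        if isinstance(r, SingleEnd):
            if len(r.seq) >= min_len:
                singles.append(r)
            continue
        ok1 = len(r.fes1) >= min_len
        ok2 = len(r.fes2) >= min_len
        if ok1 and ok2:
            pairs.append(r)
        elif ok1:
            singles.append(SingleEnd(r.read_id, 1, r.fes1, r.fes1_interval))
        elif ok2:
            singles.append(SingleEnd(r.read_id, 2, r.fes2, r.fes2_interval))
    return pairs, singles


def n50(lengths: list[int]) -> int:
    """Length at which the cumulative sorted-descending sum first reaches
    half the total."""
    if not lengths:
        raise ValueError("empty length set")
    ls = sorted(lengths, reverse=True)
    half = sum(ls) / 2.0
    acc = 0
    for x in ls:
        acc += x
        if acc >= half:
            return x
    return ls[-1]


def fes_stats(lengths: list[int]) -> dict[str, float]:
    """Per-side summary: count, N50, mean and total bases."""
    if not lengths:
        raise ValueError("no ends")
    return {
        "count": len(lengths),
        "N50": n50(lengths),
        "average_length": float(np.mean(lengths)),
        "total_bases": int(np.sum(lengths)),
    }


def process_reads(
    reads: list[tuple[str, str, str]],
    tag_sequences: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_cover: float = DEFAULT_MIN_COVER,
    min_len: int = DEFAULT_MIN_END_LEN,
) -> tuple[list[EndPair], list[SingleEnd], list[Rejection]]:
    """Run tag finding + layout resolution + length filtering over a read set."""
    found: list[EndPair | SingleEnd] = []
    rejects: list[Rejection] = []
    for rid, seq, _ in reads:
        hits = find_tags(seq, tag_sequences, min_identity, min_cover)
        res = extract_end_pair(rid, seq, hits)
        if isinstance(res, Rejection):
            rejects.append(res)
        else:
            found.append(res)
    pairs, singles = filter_ends(found, min_len)
    return pairs, singles, rejects


def summary_table(pairs: list[EndPair], singles: list[SingleEnd]) -> pd.DataFrame:
    """FES summary in the per-side layout of the published library tables."""
    l1 = [len(p.fes1) for p in pairs] + [len(s.seq) for s in singles if s.side == 1]
    l2 = [len(p.fes2) for p in pairs] + [len(s.seq) for s in singles if s.side == 2]
    row: dict[str, object] = {"FES_number": len(l1) + len(l2)}
    for side, ls in (("FES-1", l1), ("FES-2", l2)):
        if ls:
            st = fes_stats(ls)
            row[f"{side}_N50"] = st["N50"]
            row[f"{side}_average_length"] = round(st["average_length"], 1)
            row[f"{side}_total_bases"] = st["total_bases"]
        else:
            row[f"{side}_N50"] = row[f"{side}_average_length"] = row[f"{side}_total_bases"] = 0
    return pd.DataFrame([row])


def write_fes_fasta(pairs: list[EndPair], singles: list[SingleEnd], prefix: str) -> None:
    from .simulate import write_fasta

    write_fasta([(f"{p.read_id}/1", p.fes1) for p in pairs], f"{prefix}_1.fasta")
    write_fasta([(f"{p.read_id}/2", p.fes2) for p in pairs], f"{prefix}_2.fasta")
    write_fasta([(f"{s.read_id}/{s.side}", s.seq) for s in singles], f"{prefix}_single.fasta")
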