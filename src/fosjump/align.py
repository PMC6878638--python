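"""Exact k-mer anchor aligner for error-free (or near error-free) ends.

This aligner exists so the simulated pipeline is self-contained: simulated,
error-free end sequences are placed on the reference by exact 31-mer
anchoring.  Ends with a single supported placement get mapping quality 60,
ends with several supported placements (exact repeats) get 0, ends with no
anchor are unaligned.  Real-data users supply SAM/BAM/PAF from any aligner.

A light split-alignment mode chains anchors into collinear segments per read
(strand-aware), which is the input for small structural-variant signatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, kmer_codes, revcomp


@dataclass
class Placement:
    contig: str
    start: int
    end: int
    strand: str
    mapq: int


@dataclass
class Segment:
    """Collinear anchored block of a read: read [q_start, q_end) maps to
    reference [r_start, r_end) on ``strand``."""

    q_start: int
    q_end: int
    contig: str
    r_start: int
    r_end: int
    strand: str


class KmerIndex:
    """Sorted-array index of all k-mers of a reference genome."""

    def __init__(self, genome: dict[str, str], k: int = 31):
        self.k = k
        self.contigs = list(genome)
        self.lengths = [len(genome[c]) for c in self.contigs]
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])
        codes = []
        positions = []
        for i, c in enumerate(self.contigs):
            enc = encode(genome[c])
            cc = kmer_codes(enc, k)
            codes.append(cc)
            positions.append(np.arange(len(cc), dtype=np.int64) + self.offsets[i])
        codes = np.concatenate(codes) if codes else np.zeros(0, dtype=np.uint64)
        positions = np.concatenate(positions) if positions else np.zeros(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = positions[order]

    def to_local(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.contigs[i], int(gpos - self.offsets[i])

    def lookup(self, qcodes: np.ndarray, max_hits: int = 64) -> list[np.ndarray]:
        """Reference positions for each query k-mer code (capped per k-mer)."""
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        out = []
        for a, b in zip(lo, hi):
            out.append(self._pos[a:b][:max_hits] if b > a else np.zeros(0, dtype=np.int64))
        return out


def _anchor_hits(index: KmerIndex, seq: str, stride: int) -> list[tuple[int, np.ndarray]]:
    k = index.k
    if len(seq) < k:
        return []
    offs = list(range(0, len(seq) - k + 1, stride))
    if offs[-1] != len(seq) - k:
        offs.append(len(seq) - k)
    enc = encode(seq)
    codes = kmer_codes(enc, k)[offs]
    hits = index.lookup(codes)
    return [(o, h) for o, h in zip(offs, hits)]


def align_end(index: KmerIndex, seq: str, n_anchors: int = 24, min_vote: float = 0.5) -> Placement | None:
    """Place one end on the reference by exact anchor voting.

    Placements are anchor-implied read start positions, clustered within a
    small drift tolerance; a cluster supported by at least ``min_vote`` of
    the voting anchors counts.  Exactly one supported cluster -> mapq 60,
    several (repeats) -> mapq 0, none -> unaligned (None).
    """
    k = index.k
    if len(seq) < k:
        return None
    stride = max(1, (len(seq) - k) // max(n_anchors - 1, 1))
    tol = max(50, len(seq) // 20)
    votes: dict[tuple[str, int], int] = {}
    n_voting = 0
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        any_hit = False
        for o, hits in _anchor_hits(index, s, stride):
            if len(hits) == 0:
                continue
            any_hit = True
            for p in hits:
                votes[(strand, int(p) - o)] = votes.get((strand, int(p) - o), 0) + 1
        if any_hit:
            n_voting += 1
    if not votes:
        return None
    # cluster placements per strand within tol
    items = sorted(votes.items())
    clusters: list[tuple[str, int, int]] = []  # (strand, rep_placement, votes)
    for (strand, pl), v in items:
        if clusters and clusters[-1][0] == strand and pl - clusters[-1][1] <= tol:
            s0, p0, v0 = clusters[-1]
            clusters[-1] = (s0, p0 if v0 >= v else pl, v0 + v)
        else:
            clusters.append((strand, pl, v))
    total = sum(v for _, _, v in clusters)
    supported = [c for c in clusters if c[2] >= min_vote * total / max(n_voting, 1)]
    if not supported:
        supported = [max(clusters, key=lambda c: c[2])]
    best = max(supported, key=lambda c: c[2])
    strand, pl, _ = best
    contig, local = index.to_local(max(pl, 0))
    start = local
    end = start + len(seq)
    mapq = 60 if len(supported) == 1 else 0
    return Placement(contig=contig, start=start, end=end, strand=strand, mapq=mapq)


def split_align(index: KmerIndex, seq: str, stride: int = 64, max_hits: int = 4, min_anchors: int = 3) -> list[Segment]:
    """Chain exact anchors into collinear segments (split-read alignment).

    Anchors with more than ``max_hits`` reference hits (repeats) are skipped.
    Segments are maximal anchor runs with a consistent strand and diagonal;
    a new segment starts at any strand flip or diagonal jump.
    """
    k = index.k
    if len(seq) < k:
        return []
    offs = list(range(0, len(seq) - k + 1, stride))
    if offs[-1] != len(seq) - k:
        offs.append(len(seq) - k)
    enc_f = encode(seq)
    enc_r = encode(revcomp(seq))
    codes_f = kmer_codes(enc_f, k)[offs]
    codes_r = kmer_codes(enc_r, k)[::-1][offs]  # rc k-mer of the forward k-mer at each offset
    hits_f = index.lookup(codes_f, max_hits=max_hits + 1)
    hits_r = index.lookup(codes_r, max_hits=max_hits + 1)

    # one (strand, diagonal, ref_pos) anchor list in read order
    anchors: list[tuple[int, str, int, int]] = []  # (q_off, strand, diag, ref_pos)
    for o, hf, hr in zip(offs, hits_f, hits_r):
        cands = []
        if 0 < len(hf) <= max_hits:
            cands += [("+", int(p) - o, int(p)) for p in hf]
        if 0 < len(hr) <= max_hits:
            cands += [("-", int(p) + o, int(p)) for p in hr]
        for strand, diag, p in cands:
            anchors.append((o, strand, diag, p))

    tol = 100
    segs: list[Segment] = []
    open_runs: list[list[tuple[int, str, int, int]]] = []
    for a in anchors:
        o, strand, diag, p = a
        placed = False
        for run in open_runs:
            ro, rs, rd, rp = run[-1]
            if rs == strand and abs(diag - rd) <= tol and o >= ro:
                run.append(a)
                placed = True
                break
        if not placed:
            open_runs.append([a])
    for run in open_runs:
        if len(run) < min_anchors:
            continue
        q0 = run[0][0]
        q1 = run[-1][0] + k
        ps = [p for _, _, _, p in run]
        r0, r1 = min(ps), max(ps) + k
        contig, local0 = index.to_local(r0)
        contig1, _ = index.to_local(max(r1 - 1, 0))
        if contig != contig1:
            continue
        segs.append(
            Segment(
                q_start=q0,
                q_end=q1,
                contig=contig,
                r_start=local0,
                r_end=local0 + (r1 - r0),
                strand=run[0][1],
            )
        )
    segs.sort(key=lambda s: s.q_start)
    return segs


def write_paf(records: list[tuple[str, int, Placement]], contig_lengths: dict[str, int], path: str) -> None:
    """Minimal PAF for end placements: (read_id, read_len, placement) rows."""
    with open(path, "w") as fh:
        for rid, rlen, p in records:
            row = [
                rid,
                rlen,
                0,
                rlen,
                p.strand,
                p.contig,
                contig_lengths[p.contig],
                p.start,
                p.end,
                rlen,
                rlen,
                p.mapq,
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")
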