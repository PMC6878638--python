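"""Structural-rearrangement calling from Fosmid jumps and long single ends.

Two complementary signals are used, mirroring how jumping libraries expose
rearrangements relative to a reference assembly:

* **large events** (tens of kb) from clustered discordant paired-end jumps:
  convergent pairs spanning too far are deletions (size = median span minus
  the library insert mean), convergent pairs spanning too short are tandem
  duplications (size = insert mean minus median span), orientation anomalies
  are inversions, and inter-contig pairs are translocations;
* **small events** (tens of bp to several kb) from split alignments of long
  single ends used as whole-genome reads: a reference gap between adjacent
  collinear segments is a deletion, overlapping reference segments are a
  duplication, extra read sequence is an insertion, and a strand flip is an
  inversion whose reference interval spans the flipped segment.

Support is reported both without duplicates ("independent" pairs/reads, used
against the minimum-support threshold) and with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Segment
from .classify import JumpRecord

DEFAULT_MIN_SUPPORT_LARGE = 9
DEFAULT_MIN_SUPPORT_SMALL = 7
DEFAULT_MIN_SMALL_LEN = 30
DEFAULT_SMALL_CLUSTER_DIST = 500


@dataclass
class DiscordantCluster:
    label: str
    orientation: str
    contigs: tuple[str, str]
    members: list[JumpRecord]
    left_footprint: tuple[int, int]
    right_footprint: tuple[int, int]

    @property
    def support_dup(self) -> int:
        return len(self.members)

    @property
    def support_nondup(self) -> int:
        return sum(1 for m in self.members if not m.duplicate)


@dataclass
class SVCall:
    type: str  # deletion | duplication | inversion | translocation | insertion
    chrom: str
    start: int  # 0-based half-open internally; serialised 1-based inclusive
    end: int
    length: int | None
    support_nondup: int
    support_dup: int
    chrom2: str | None = None
    pos2: int | None = None
    source: str = "paired"  # paired | split


def _iv_dist(a: tuple[int, int], b: tuple[int, int]) -> int:
    if a[1] <= b[0]:
        return b[0] - a[1]
    if b[1] <= a[0]:
        return a[0] - b[1]
    return 0


def jumps_linked(
    a: JumpRecord,
    b: JumpRecord,
    merge_dist: float = 6_600.0,
    junction_window: float = 45_000.0,
) -> bool:
    """Linkage rule for discordant clustering.

    Intra-contig pairs supporting the same event share the rearranged
    interval inside their inner gaps, so they link when the inner-gap
    intervals [left.end, right.start) lie within ``merge_dist`` of each
    other (overlap included).  Inter-contig pairs link when their implied
    junction positions on both contigs agree to within ``junction_window``
    (the junction can sit anywhere up to one insert length from an end, so
    the window defaults to the insert-selection upper bound).
    """
    if a.span is None or b.span is None:
        return (
            abs(a.left.end - b.left.end) <= junction_window
            and abs(a.right.start - b.right.start) <= junction_window
        )
    ga = tuple(sorted((a.left.end, a.right.start)))
    gb = tuple(sorted((b.left.end, b.right.start)))
    return _iv_dist(ga, gb) <= merge_dist


def cluster_discordant(
    jumps: list[JumpRecord],
    merge_dist: float = 6_600.0,
    junction_window: float = 45_000.0,
) -> list[DiscordantCluster]:
    """Single-linkage clustering of same-signature discordant jumps.

    Two jumps join when they share (label, orientation, contig pair) and
    satisfy :func:`jumps_linked`.  Duplicates are kept (both support counts
    are reported per cluster).
    """
    disc = [j for j in jumps if j.label != "correct"]
    groups: dict[tuple, list[JumpRecord]] = {}
    for j in disc:
        groups.setdefault((j.label, j.orientation, j.left.contig, j.right.contig), []).append(j)
    clusters: list[DiscordantCluster] = []
    for (label, orientation, c1, c2), members in sorted(groups.items()):
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for k in range(i + 1, n):
                if jumps_linked(members[i], members[k], merge_dist, junction_window):
                    parent[find(i)] = find(k)
        comp: dict[int, list[JumpRecord]] = {}
        for i in range(n):
            comp.setdefault(find(i), []).append(members[i])
        for ms in comp.values():
            clusters.append(
                DiscordantCluster(
                    label=label,
                    orientation=orientation,
                    contigs=(c1, c2),
                    members=ms,
                    left_footprint=(min(m.left.start for m in ms), max(m.left.end for m in ms)),
                    right_footprint=(min(m.right.start for m in ms), max(m.right.end for m in ms)),
                )
            )
    clusters.sort(key=lambda c: (c.contigs, c.left_footprint))
    return clusters


def call_large_svs(
    clusters: list[DiscordantCluster],
    insert_mean: float = 38_000.0,
    insert_sd: float = 2_200.0,
    min_support: int = DEFAULT_MIN_SUPPORT_LARGE,
    tandem_as_duplication: bool = False,
) -> list[SVCall]:
    """Interpret discordant clusters as rearrangements.

    Sizes come from the median member span against the insert mean; the
    breakpoint interval is the inner-gap region shared by the members
    (inner boundary convention).  Clusters below ``min_support`` independent
    (non-duplicate) pairs are suppressed.  By default both orientation
    anomalies (divergent and tandem) are read as inversion signatures;
    ``tandem_as_duplication`` reads tandem clusters as duplications instead.
    """
    calls: list[SVCall] = []
    for c in clusters:
        if c.support_nondup < min_support:
            continue
        spans = [m.span for m in c.members if m.span is not None]
        med = float(np.median(spans)) if spans else 0.0
        inner_left = max(m.left.end for m in c.members)
        inner_right = min(m.right.start for m in c.members)
        if c.label == "chim_intercontig":
            pos1 = int(np.median([m.left.end for m in c.members]))
            pos2 = int(np.median([m.right.start for m in c.members]))
            calls.append(
                SVCall(
                    type="translocation",
                    chrom=c.contigs[0],
                    start=pos1,
                    end=pos1 + 1,
                    length=None,
                    support_nondup=c.support_nondup,
                    support_dup=c.support_dup,
                    chrom2=c.contigs[1],
                    pos2=pos2,
                )
            )
            continue
        if c.label == "chim_long" and c.orientation == "convergent":
            svtype = "deletion"
            size = int(round(med - insert_mean))
        elif c.label == "chim_short" and c.orientation == "convergent":
            svtype = "duplication"
            size = int(round(insert_mean - med))
        elif c.label == "chim_orientation":
            if c.orientation == "tandem" and tandem_as_duplication:
                svtype = "duplication"
                size = max(int(round(abs(insert_mean - med))), 1)
            else:
                svtype = "inversion"
                size = max(inner_right - inner_left, 1)
        else:
            continue
        if size <= 0:
            continue
        start = inner_left if inner_left < inner_right else int(np.median([m.left.end for m in c.members]))
        calls.append(
            SVCall(
                type=svtype,
                chrom=c.contigs[0],
                start=start,
                end=start + size,
                length=size,
                support_nondup=c.support_nondup,
                support_dup=c.support_dup,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# split-alignment (single-end) signatures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSignature:
    type: str
    contig: str
    start: int
    end: int
    length: int
    read_id: str


def extract_split_signatures(read_id: str, segments: list[Segment], min_len: int = DEFAULT_MIN_SMALL_LEN) -> list[SplitSignature]:
    """Within-read rearrangement signatures between adjacent split segments."""
    sigs: list[SplitSignature] = []
    for a, b in zip(segments, segments[1:]):
        if a.contig != b.contig:
            continue
        read_gap = b.q_start - a.q_end
        if a.strand != b.strand:
            # inversion: the flipped segment lies inside the inverted region,
            # so the signature interval spans the whole inversion
            if a.strand == "+" and b.strand == "-":
                s, e = a.r_end, b.r_end
            else:
                s, e = a.r_start, b.r_start
            s, e = min(s, e), max(s, e)
            if e - s >= min_len:
                sigs.append(SplitSignature("inversion", a.contig, s, e, e - s, read_id))
            continue
        if a.strand == "-":
            ref_gap = a.r_start - b.r_end
            s, e = b.r_end, a.r_start
        else:
            ref_gap = b.r_start - a.r_end
            s, e = a.r_end, b.r_start
        delta = ref_gap - read_gap
        if delta >= min_len:
            sigs.append(SplitSignature("deletion", a.contig, min(s, e), min(s, e) + delta, delta, read_id))
        elif ref_gap <= -min_len:
            # overlapping reference coverage: tandem duplication
            length = -ref_gap
            pos = e if a.strand == "+" else s
            sigs.append(SplitSignature("duplication", a.contig, pos, pos + length, length, read_id))
        elif read_gap - max(ref_gap, 0) >= min_len:
            length = read_gap - max(ref_gap, 0)
            sigs.append(SplitSignature("insertion", a.contig, s, s + 1, length, read_id))
    return sigs


def call_small_svs(
    signatures: list[SplitSignature],
    min_support: int = DEFAULT_MIN_SUPPORT_SMALL,
    cluster_dist: int = DEFAULT_SMALL_CLUSTER_DIST,
) -> list[SVCall]:
    """Cluster split signatures by type and position and call supported events.

    Signatures of one type on one contig join a cluster when both their start
    and end lie within ``cluster_dist`` of a member; a call needs at least
    ``min_support`` distinct supporting reads.
    """
    groups: dict[tuple[str, str], list[SplitSignature]] = {}
    for s in signatures:
        groups.setdefault((s.type, s.contig), []).append(s)
    calls: list[SVCall] = []
    for (svtype, contig), sigs in sorted(groups.items()):
        sigs = sorted(sigs, key=lambda s: (s.start, s.end))
        n = len(sigs)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for k in range(i + 1, n):
                if sigs[k].start - sigs[i].start > cluster_dist:
                    break
                if abs(sigs[k].end - sigs[i].end) <= cluster_dist:
                    parent[find(i)] = find(k)
        comp: dict[int, list[SplitSignature]] = {}
        for i in range(n):
            comp.setdefault(find(i), []).append(sigs[i])
        for ms in comp.values():
            reads = {m.read_id for m in ms}
            if len(reads) < min_support:
                continue
            start = int(np.median([m.start for m in ms]))
            end = int(np.median([m.end for m in ms]))
            length = int(np.median([m.length for m in ms]))
            calls.append(
                SVCall(
                    type=svtype,
                    chrom=contig,
                    start=start,
                    end=max(end, start + 1),
                    length=length,
                    support_nondup=len(reads),
                    support_dup=len(ms),
                    source="split",
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_SVTYPE_CODE = {"deletion": "DEL", "duplication": "DUP", "inversion": "INV", "insertion": "INS"}


def write_sv_vcf(calls: list[SVCall], contig_lengths: dict[str, int], path: str) -> None:
    """VCF 4.2 with SVTYPE/SVLEN/END/SUPPORT info; translocations as BND pairs."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads including duplicates">',
        '##INFO=<ID=SUPPORT_NONDUP,Number=1,Type=Integer,Description="Independent supporting reads">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=INS,Description="Insertion">',
    ]
    for c, L in contig_lengths.items():
        lines.append(f"##contig=<ID={c},length={L}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    bnd = 0
    for i, c in enumerate(calls, 1):
        support = f"SUPPORT={c.support_dup};SUPPORT_NONDUP={c.support_nondup}"
        if c.type == "translocation":
            bnd += 1
            id1, id2 = f"BND{bnd}_1", f"BND{bnd}_2"
            alt1 = f"N]{c.chrom2}:{c.pos2 + 1}]"
            alt2 = f"N]{c.chrom}:{c.start + 1}]"
            lines.append(f"{c.chrom}\t{c.start + 1}\t{id1}\tN\t{alt1}\t.\tPASS\tSVTYPE=BND;MATEID={id2};{support}")
            lines.append(f"{c.chrom2}\t{c.pos2 + 1}\t{id2}\tN\t{alt2}\t.\tPASS\tSVTYPE=BND;MATEID={id1};{support}")
            continue
        code = _SVTYPE_CODE[c.type]
        svlen = c.length if c.length is not None else c.end - c.start
        if code == "DEL":
            svlen = -svlen
        lines.append(
            f"{c.chrom}\t{c.start + 1}\tSV{i}\tN\t<{code}>\t.\tPASS\t"
            f"SVTYPE={code};END={c.end};SVLEN={svlen};{support}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sv_vcf(path: str) -> list[SVCall]:
    """Parse a VCF written by :func:`write_sv_vcf` back into calls."""
    name = {v: k for k, v in _SVTYPE_CODE.items()}
    calls: list[SVCall] = []
    bnd_seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            sup = int(info.get("SUPPORT", 0))
            sup_nd = int(info.get("SUPPORT_NONDUP", 0))
            if info.get("SVTYPE") == "BND":
                if f[2] in bnd_seen:
                    continue
                bnd_seen.add(info.get("MATEID", ""))
                mate = f[4].split("]")[1].split(":")
                calls.append(
                    SVCall(
                        type="translocation",
                        chrom=f[0],
                        start=int(f[1]) - 1,
                        end=int(f[1]),
                        length=None,
                        support_nondup=sup_nd,
                        support_dup=sup,
                        chrom2=mate[0],
                        pos2=int(mate[1]) - 1,
                    )
                )
                continue
            svtype = name[info["SVTYPE"]]
            svlen = abs(int(info["SVLEN"]))
            calls.append(
                SVCall(
                    type=svtype,
                    chrom=f[0],
                    start=int(f[1]) - 1,
                    end=int(info["END"]),
                    length=svlen,
                    support_nondup=sup_nd,
                    support_dup=sup,
                )
            )
    return calls


def sv_table(calls: list[SVCall]):
    """Event table mirroring the published rearrangement-table columns."""
    import pandas as pd

    rows = []
    for c in calls:
        if c.type == "translocation":
            coord = f"{c.chrom}:{c.start + 1};{c.chrom2}:{c.pos2 + 1}"
            length = "Non"
        else:
            coord = f"{c.chrom}:{c.start + 1}-{c.end}"
            length = c.length
        rows.append(
            {
                "support_nondup": c.support_nondup,
                "support_dup": c.support_dup,
                "sv_type": c.type,
                "sv_length": length,
                "coordinate": coord,
            }
        )
    return pd.DataFrame(rows)
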