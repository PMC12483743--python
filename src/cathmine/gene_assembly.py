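"""Exon assembly for cathelicidin loci.

Turns a scanned locus into a four-exon gene model. The architecture is the
canonical cathelicidin layout: a variable-length exon 1 (signal peptide +
start of the cathelin domain), exon 2 of 108 bp and exon 3 of 72 bp (the
conserved core of the cathelin domain), and a hypervariable exon 4 carrying
the mature peptide. Introns obey the GT..AG rule, with GTGAG/GTAAG the
preferred donors and CAG/TAG the preferred acceptors.

Exon 4 is located by an explicit repair procedure: every plausible acceptor
downstream of exon 3 is considered, the reading frame is propagated across
the junction, and candidates are scored by how well the first residues of
the exon-4 translation continue the conserved-domain tail, plus soft
bonuses for preferred acceptor trimers and typical intron-3 lengths.
Structural lesions (missing exon 2, premature stops, non-AG acceptors,
N-gaps) are recorded as defect flags that determine the gene status.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .core_io import (
    CathmineError,
    DefectFlag,
    DefectKind,
    GeneModel,
    GeneStatus,
    Interval,
    IntronRecord,
    NONFUNCTIONAL_KINDS,
    Prepropeptide,
    SequenceRecord,
    reverse_complement,
    translate,
)
from .locus_search import Locus, load_matrix, smith_waterman

# ---------------------------------------------------------------------------
# configuration


@dataclass
class SpliceConfig:
    donor_required_prefix: str = "GT"
    preferred_donor5: tuple[str, ...] = ("GTGAG", "GTAAG")
    acceptor_required_suffix: str = "AG"
    preferred_acceptor3: tuple[str, ...] = ("CAG", "TAG")
    #: per-intron (min, max) length bounds used when searching splice sites
    intron_len_bounds: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (200, 1500), 2: (100, 400), 3: (300, 1500)}
    )

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.intron_len_bounds.items():
            if not (0 < lo < hi):
                raise CathmineError(f"intron {k}: invalid length bounds ({lo}, {hi})")


@dataclass
class GeneArchitecture:
    exon2_len: int = 108
    exon3_len: int = 72
    exon1_len_range: tuple[int, int] = (150, 260)
    exon4_max_len: int = 700

    def __post_init__(self) -> None:
        if self.exon2_len % 3 or self.exon3_len % 3:
            raise CathmineError("exon 2/3 lengths must be codon multiples")
        if min(self.exon2_len, self.exon3_len, self.exon4_max_len) <= 0:
            raise CathmineError("architecture lengths must be positive")


@dataclass
class AssemblyConfig:
    """Scoring knobs for exon mapping and exon-4 repair."""

    exon2_min_score: float = 60.0
    exon3_min_score: float = 40.0
    # core exons encode the probe's mid-region; alignments starting before
    # these probe residues (derived from the minimum exon-1 length) are
    # rejected as exon-1 shadows
    exon2_min_probe_start: int = 40
    exon2_max_probe_start: int = 95
    exon3_min_probe_start: int = 70
    exon3_max_probe_start: int = 130
    exon1_probe_identity: float = 0.5  # over the first exon1_identity_window residues
    exon1_identity_window: int = 20
    exon1_len_penalty: float = 4.0  # per residue off the probe-implied exon-1 length
    donor_pref_bonus: float = 6.0
    acceptor_bonus: float = 5.0
    intron3_preferred: tuple[int, int] = (500, 600)
    intron_len_penalty_rate: float = 0.01  # per nt outside the preferred band
    tail_k: int = 12  # residues of exon-4 translation scored vs the domain tail
    tail_min_score: float = 25.0
    anomalous_margin: float = 8.0  # non-AG candidate must beat AG best by this
    polya_signal: str = "AATAAA"
    polya_window: int = 1000
    n_run_min: int = 10
    signal_len: int = 29
    cathelin_exon4_residues: int = 4


# ---------------------------------------------------------------------------
# splice-site search


def find_splice_sites(
    gdna: str,
    window: Interval,
    kind: str,
    splice: SpliceConfig | None = None,
) -> list[int]:
    """Ranked candidate splice positions inside ``window``.

    For ``kind='donor'`` positions are intron starts (first base of GT);
    for ``kind='acceptor'`` positions are exon starts (just past the AG).
    Preferred donor pentamers / acceptor trimers rank first (in configured
    order), then proximity to the window centre.
    """
    splice = splice or SpliceConfig()
    if len(window) == 0 or window.start >= len(gdna):
        raise CathmineError("find_splice_sites: empty window")
    centre = (window.start + window.end) / 2
    hits: list[tuple[int, float, int]] = []
    if kind == "donor":
        for p in range(window.start, min(window.end, len(gdna) - 1)):
            if gdna[p : p + 2] != splice.donor_required_prefix:
                continue
            penta = gdna[p : p + 5]
            try:
                rank = splice.preferred_donor5.index(penta)
            except ValueError:
                rank = len(splice.preferred_donor5)
            hits.append((rank, abs(p - centre), p))
    elif kind == "acceptor":
        for p in range(max(window.start, 2), window.end):
            if gdna[p - 2 : p] != splice.acceptor_required_suffix:
                continue
            tri = gdna[p - 3 : p]
            try:
                rank = splice.preferred_acceptor3.index(tri)
            except ValueError:
                rank = len(splice.preferred_acceptor3)
            hits.append((rank, abs(p - centre), p))
    else:
        raise CathmineError(f"kind must be donor or acceptor, got {kind!r}")
    hits.sort()
    return [p for _, _, p in hits]


# ---------------------------------------------------------------------------
# assembly context (gene-orientation workspace)


@dataclass
class AssemblyContext:
    """Locus sequence in gene orientation plus local exon coordinates."""

    source_id: str
    strand: str
    gseq: str  # full source sequence in gene orientation
    g_off: int  # locus start within gseq
    g_len: int  # locus length
    exon1: tuple[int, int] | None = None  # local coords within the locus
    exon2: tuple[int, int] | None = None
    exon3: tuple[int, int] | None = None
    exon4: tuple[int, int] | None = None
    probe_tail_start: int | None = None  # probe residue where exon 3 alignment ends
    defects: list[DefectFlag] = field(default_factory=list)

    @property
    def lseq(self) -> str:
        return self.gseq[self.g_off : self.g_off + self.g_len]

    def to_forward(self, local: tuple[int, int]) -> Interval:
        """Map local gene-orientation coords back to the forward strand."""
        a = self.g_off + local[0]
        b = self.g_off + local[1]
        if self.strand == "+":
            return Interval(a, b, "+")
        L = len(self.gseq)
        return Interval(L - b, L - a, "-")


def _best_frame_score(segment: str, probe: str) -> tuple[float, int, int, int, int]:
    """Best SW score of any reading frame of ``segment`` vs the probe.

    Returns (score, frame, probe_alignment_start, probe_alignment_end,
    segment_residues_aligned).
    """
    best = (-1.0, 0, 0, 0, 0)
    for f in range(3):
        prot = translate(segment, f)
        if not prot:
            continue
        res = smith_waterman(prot, probe)
        if res.score > best[0]:
            best = (res.score, f, res.b_span[0], res.b_span[1],
                    res.a_span[1] - res.a_span[0])
    return best


def _find_core_exon(
    lseq: str,
    exon_len: int,
    probe: str,
    splice: SpliceConfig,
    min_score: float,
    search_range: tuple[int, int] | None = None,
    require_flanks: bool = True,
    min_probe_start: int = 0,
    max_probe_start: int = 10_000,
) -> tuple[int, float, int, int] | None:
    """Best ``exon_len`` segment whose translation matches the probe.

    Returns (start, score, frame, probe_start, probe_end) or None. With
    ``require_flanks`` the segment must be preceded by an AG acceptor and
    followed by a GT donor.
    """
    lo = search_range[0] if search_range else 2
    hi = search_range[1] if search_range else len(lseq) - exon_len - 2
    lo = max(lo, 2)
    hi = min(hi, len(lseq) - exon_len - 2)
    best: tuple[int, float, int, int, int] | None = None
    for i in range(lo, hi + 1):
        if require_flanks:
            if lseq[i - 2 : i] != splice.acceptor_required_suffix:
                continue
            if lseq[i + exon_len : i + exon_len + 2] != splice.donor_required_prefix:
                continue
        score, frame, q_start, q_end, a_len = _best_frame_score(
            lseq[i : i + exon_len], probe
        )
        if score < min_score:
            continue
        if not (min_probe_start <= q_start <= max_probe_start):
            # the core exons encode the probe's mid-region; alignments
            # starting in the signal region are exon-1 shadows, ones deep in
            # the C-terminal region are exon-4 shadows
            continue
        if a_len < exon_len // 3 - 2:
            # the whole exon must align: partial-overlap impostors (e.g. a
            # window straddling an intron boundary) are rejected
            continue
        if best is None or score > best[1]:
            best = (i, score, frame, q_start, q_end)
    return best


def map_core_exons(
    gdna: SequenceRecord,
    locus: Locus,
    probe: SequenceRecord,
    splice: SpliceConfig | None = None,
    arch: GeneArchitecture | None = None,
    config: AssemblyConfig | None = None,
) -> AssemblyContext:
    """Map exons 1-3 inside a locus; record defects for missing pieces."""
    splice = splice or SpliceConfig()
    arch = arch or GeneArchitecture()
    config = config or AssemblyConfig()
    if not locus.hsps:
        raise CathmineError("map_core_exons: locus has no HSPs")
    strand = locus.strand
    L = len(gdna.residues)
    gseq = gdna.residues if strand == "+" else reverse_complement(gdna.residues)
    if strand == "+":
        g_off = locus.interval.start
    else:
        g_off = L - locus.interval.end
    ctx = AssemblyContext(
        source_id=gdna.id, strand=strand, gseq=gseq, g_off=g_off,
        g_len=len(locus.interval),
    )
    lseq = ctx.lseq
    pseq = probe.residues

    # --- exon 2 (108 bp): AG..segment..GT whose translation hits the
    # probe's mid-region, anywhere in the locus
    hit2 = _find_core_exon(
        lseq, arch.exon2_len, pseq, splice, config.exon2_min_score,
        min_probe_start=config.exon2_min_probe_start,
        max_probe_start=config.exon2_max_probe_start,
    )
    if hit2 is not None:
        i = hit2[0]
        ctx.exon2 = (i, i + arch.exon2_len)

    # --- exon 3 (72 bp): downstream of exon 2 when available
    i2lo, i2hi = splice.intron_len_bounds[2]
    rng3 = (ctx.exon2[1] + i2lo, ctx.exon2[1] + i2hi) if ctx.exon2 is not None else None
    hit3 = _find_core_exon(
        lseq, arch.exon3_len, pseq, splice, config.exon3_min_score,
        search_range=rng3, min_probe_start=config.exon3_min_probe_start,
        max_probe_start=config.exon3_max_probe_start,
    )
    if hit3 is None and rng3 is not None:
        relaxed = _find_core_exon(
            lseq, arch.exon3_len, pseq, splice, config.exon3_min_score,
            search_range=rng3, require_flanks=False,
            min_probe_start=config.exon3_min_probe_start,
            max_probe_start=config.exon3_max_probe_start,
        )
        if relaxed is not None:
            j = relaxed[0]
            ctx.exon3 = (j, j + arch.exon3_len)
            ctx.probe_tail_start = relaxed[4]
            ctx.defects.append(
                DefectFlag(
                    DefectKind.anomalous_acceptor,
                    where=ctx.to_forward(ctx.exon3),
                    note=f"exon 3 flank not GT..AG; terminal triplet {lseq[j-3:j]!r}",
                )
            )
        else:
            hit3 = _find_core_exon(
                lseq, arch.exon3_len, pseq, splice, config.exon3_min_score,
                min_probe_start=config.exon3_min_probe_start,
                max_probe_start=config.exon3_max_probe_start,
            )
    if hit3 is not None:
        j = hit3[0]
        ctx.exon3 = (j, j + arch.exon3_len)
        ctx.probe_tail_start = hit3[4]
    if ctx.exon3 is None and not ctx.defects:
        ctx.defects.append(
            DefectFlag(DefectKind.truncated_scaffold, note="exon 3 not found")
        )

    # consistency: exon 2 must sit one intron-2 upstream of exon 3; a
    # high-scoring shadow elsewhere (e.g. in the exon-4 region) loses to the
    # spacing constraint once exon 3 is placed
    if ctx.exon2 is not None and ctx.exon3 is not None:
        gap = ctx.exon3[0] - ctx.exon2[1]
        if not (i2lo <= gap <= i2hi):
            w2 = (
                ctx.exon3[0] - i2hi - arch.exon2_len,
                ctx.exon3[0] - i2lo - arch.exon2_len,
            )
            redo = _find_core_exon(
                lseq, arch.exon2_len, pseq, splice, config.exon2_min_score,
                search_range=w2,
                min_probe_start=config.exon2_min_probe_start,
                max_probe_start=config.exon2_max_probe_start,
            )
            hit2 = redo
            ctx.exon2 = (redo[0], redo[0] + arch.exon2_len) if redo else None

    # --- exon 2 lesion calls, once exon 3 pins where exon 2 ought to sit
    if ctx.exon2 is None:
        relaxed2 = None
        if ctx.exon3 is not None:
            w2 = (
                ctx.exon3[0] - i2hi - arch.exon2_len,
                ctx.exon3[0] - i2lo - arch.exon2_len,
            )
            relaxed2 = _find_core_exon(
                lseq, arch.exon2_len, pseq, splice, config.exon2_min_score,
                search_range=w2, require_flanks=False,
                min_probe_start=config.exon2_min_probe_start,
                max_probe_start=config.exon2_max_probe_start,
            )
        if relaxed2 is not None:
            i = relaxed2[0]
            ctx.exon2 = (i, i + arch.exon2_len)
            ctx.defects.append(
                DefectFlag(
                    DefectKind.anomalous_acceptor,
                    where=ctx.to_forward(ctx.exon2),
                    note=f"exon 2 flank not GT..AG; terminal triplet {lseq[i-3:i]!r}",
                )
            )
        else:
            ctx.defects.append(
                DefectFlag(DefectKind.missing_exon2, note="no 108 bp exon-2 candidate")
            )

    # --- exon 1: ATG..donor upstream of the first mapped core exon
    anchor = ctx.exon2[0] if ctx.exon2 is not None else (
        ctx.exon3[0] if ctx.exon3 is not None else None
    )
    if anchor is not None:
        i1lo, i1hi = splice.intron_len_bounds[1]
        if ctx.exon2 is None:
            # exon 2 lost: the gap spans introns 1+2 (and the lesion)
            i1lo, i1hi = i1lo + i2lo, i1hi + i2hi
        frame2 = hit2[2] if (ctx.exon2 is not None and hit2 is not None) else None
        q2_start = hit2[3] if (ctx.exon2 is not None and hit2 is not None) else None
        e1 = _find_exon1(
            lseq, anchor, (i1lo, i1hi), arch, splice, config, pseq, frame2, q2_start
        )
        if e1 is not None:
            ctx.exon1 = e1
        else:
            ctx.defects.append(
                DefectFlag(DefectKind.truncated_scaffold, note="exon 1 not found")
            )
    return ctx


def _find_exon1(
    lseq: str,
    anchor: int,
    intron1_bounds: tuple[int, int],
    arch: GeneArchitecture,
    splice: SpliceConfig,
    config: AssemblyConfig,
    probe: str,
    exon2_frame: int | None,
    exon2_probe_start: int | None,
) -> tuple[int, int] | None:
    """Locate exon 1 as ATG..donor with translation matching the probe start.

    The probe is collinear with the exons, so when exon 2 is mapped its
    probe-alignment start pins the expected exon-1 translation length;
    candidates are penalized per residue of deviation. This stops local
    alignment from silently extending exon 1 into intron 1.
    """
    i1lo, i1hi = intron1_bounds
    e1lo, e1hi = arch.exon1_len_range
    w = config.exon1_identity_window
    best: tuple[float, bool, int, int] | None = None
    d_lo = max(0, anchor - i1hi)
    d_hi = anchor - i1lo
    for d in range(d_lo, d_hi + 1):
        if lseq[d : d + 2] != splice.donor_required_prefix:
            continue
        penta = lseq[d : d + 5]
        donor_bonus = (
            config.donor_pref_bonus if penta in splice.preferred_donor5 else 0.0
        )
        for m in range(max(0, d - e1hi), d - e1lo + 1):
            if lseq[m : m + 3] != "ATG":
                continue
            e1len = d - m
            if exon2_frame is not None and e1len % 3 != (3 - exon2_frame) % 3:
                continue
            t1 = translate(lseq[m:d], 0)
            if len(t1) < w:
                continue
            ident = sum(a == b for a, b in zip(t1[:w], probe[:w])) / w
            if ident < config.exon1_probe_identity:
                continue
            score = smith_waterman(t1, probe).score + donor_bonus
            if exon2_probe_start is not None:
                expected = exon2_probe_start - (1 if e1len % 3 else 0)
                score -= config.exon1_len_penalty * abs(len(t1) - expected)
            key = (score, penta in splice.preferred_donor5, -m, -d)
            if best is None or key > best:
                best = key
    if best is None:
        return None
    return (-best[2], -best[3])


# ---------------------------------------------------------------------------
# exon-4 repair


def _tail_prefix_score(head: str, profile: str, matrix: str = "BLOSUM62") -> float:
    """Position-anchored (ungapped) score of a candidate exon-4 head against
    the conserved-domain tail profile.

    Unlike a local alignment, the head must line up with the profile from its
    first residue (a one-residue slack absorbs the split junction codon), so
    an acceptor shifted a few codons away cannot hide its out-of-register
    prefix by clipping it.
    """
    alphabet, S = load_matrix(matrix)
    idx = {ch: i for i, ch in enumerate(alphabet)}
    x = idx.get("X", 0)
    best = float("-inf")
    for shift in (-1, 0, 1):
        score = 0.0
        n = 0
        for j, pj in enumerate(profile):
            k = j + shift
            if 0 <= k < len(head):
                score += float(S[idx.get(head[k], x), idx.get(pj, x)])
                n += 1
        if n >= min(8, len(profile)) and score > best:
            best = score
    return best if best != float("-inf") else 0.0


@dataclass
class Exon4Candidate:
    acceptor_at: int  # local exon-4 start (just past the acceptor AG)
    exon4: tuple[int, int]  # local coords, includes the stop codon
    translation: str  # in-phase translation ending at the first stop
    domain_tail_score: float
    acceptor_bonus: float
    intron_len_penalty: float
    has_polya_downstream: bool
    acceptor_triplet: str
    canonical_acceptor: bool
    complete: bool  # an in-frame stop was found within the length cap

    @property
    def total_score(self) -> float:
        return self.domain_tail_score + self.acceptor_bonus - self.intron_len_penalty


def repair_exon4(
    ctx: AssemblyContext,
    probe: SequenceRecord,
    splice: SpliceConfig | None = None,
    arch: GeneArchitecture | None = None,
    config: AssemblyConfig | None = None,
    domain_tail_profile: str | None = None,
) -> list[Exon4Candidate]:
    """Rank candidate fourth exons downstream of exon 3.

    Every acceptor within the intron-3 length window opens a candidate whose
    translation continues the established reading frame to the first stop.
    Candidates are scored by the conserved-domain tail continuing into
    exon 4, a preferred-acceptor bonus, and an intron-length penalty outside
    the typical 500-600 bp band. If no AG acceptor yields a plausible tail,
    a relaxed scan flags an anomalous (non-AG) acceptor.
    """
    splice = splice or SpliceConfig()
    arch = arch or GeneArchitecture()
    config = config or AssemblyConfig()
    if ctx.exon3 is None or ctx.exon1 is None:
        raise CathmineError("repair_exon4: exons 1-3 must be mapped first")
    lseq = ctx.lseq
    e3_end = ctx.exon3[1]
    if domain_tail_profile is None:
        qs = ctx.probe_tail_start or 0
        domain_tail_profile = probe.residues[qs : qs + config.tail_k]
        if len(domain_tail_profile) < 4:
            domain_tail_profile = probe.residues[-config.tail_k :]
    # phase carried across the exon3/exon4 junction
    cds_before = (ctx.exon1[1] - ctx.exon1[0]) + (ctx.exon2[1] - ctx.exon2[0] if ctx.exon2 else 0) + (ctx.exon3[1] - ctx.exon3[0])
    rem = cds_before % 3
    carry = lseq[e3_end - rem : e3_end] if rem else ""
    i3lo, i3hi = splice.intron_len_bounds[3]
    window = Interval(min(e3_end + i3lo, len(lseq) - 1), min(e3_end + i3hi, len(lseq)))

    def build(a: int, require_ag: bool) -> Exon4Candidate | None:
        if require_ag and lseq[a - 2 : a] != splice.acceptor_required_suffix:
            return None
        chunk = carry + lseq[a : a + arch.exon4_max_len + 3]
        prot = translate(chunk, 0)
        stop = prot.find("*")
        complete = stop != -1
        if complete:
            t4 = prot[: stop + 1]
            e4_end = a - rem + 3 * (stop + 1)
        else:
            t4 = prot
            e4_end = min(a + arch.exon4_max_len, len(lseq))
        head = t4.rstrip("*")[: config.tail_k]
        tail_score = _tail_prefix_score(head, domain_tail_profile) if head else 0.0
        tri = lseq[a - 3 : a]
        bonus = config.acceptor_bonus if tri in splice.preferred_acceptor3 else 0.0
        ilen = a - e3_end
        plo, phi = config.intron3_preferred
        outside = max(0, plo - ilen) + max(0, ilen - phi)
        penalty = config.intron_len_penalty_rate * outside
        polya = complete and (
            config.polya_signal in lseq[e4_end : e4_end + config.polya_window]
        )
        return Exon4Candidate(
            acceptor_at=a,
            exon4=(a, e4_end),
            translation=t4,
            domain_tail_score=tail_score,
            acceptor_bonus=bonus,
            intron_len_penalty=penalty,
            has_polya_downstream=bool(polya),
            acceptor_triplet=tri,
            canonical_acceptor=lseq[a - 2 : a] == splice.acceptor_required_suffix,
            complete=complete,
        )

    candidates: list[Exon4Candidate] = []
    if len(window):
        for a in find_splice_sites(lseq, window, "acceptor", splice):
            cand = build(a, require_ag=True)
            if cand is not None:
                candidates.append(cand)
    # hard constraint first (an in-frame stop), then the soft score
    candidates.sort(key=lambda c: (c.complete, c.total_score, -c.acceptor_at), reverse=True)
    good = [c for c in candidates if c.complete and c.domain_tail_score >= config.tail_min_score]
    if len(window):
        # relaxed scan over every position: when the real acceptor has lost
        # its AG, the true exon 4 still announces itself by a domain tail
        # that clearly outscores every AG-gated candidate
        relaxed: list[Exon4Candidate] = []
        for a in range(window.start, window.end):
            cand = build(a, require_ag=False)
            if cand is not None and cand.complete and cand.domain_tail_score >= config.tail_min_score:
                relaxed.append(cand)
        relaxed.sort(key=lambda c: (c.total_score, -c.acceptor_at), reverse=True)
        best_strict = good[0].total_score if good else float("-inf")
        if relaxed and not relaxed[0].canonical_acceptor and (
            relaxed[0].total_score > best_strict + config.anomalous_margin
        ):
            top = relaxed[0]
            ctx.defects.append(
                DefectFlag(
                    DefectKind.anomalous_acceptor,
                    where=ctx.to_forward((top.acceptor_at - 3, top.acceptor_at)),
                    note=f"intron 3 terminal triplet {top.acceptor_triplet!r}",
                )
            )
            candidates = [top] + candidates
    return candidates


# ---------------------------------------------------------------------------
# full assembly


def _scan_n_gaps(ctx: AssemblyContext, config: AssemblyConfig, span: tuple[int, int]) -> None:
    lseq = ctx.lseq
    lo = max(0, span[0])
    hi = min(len(lseq), span[1])
    m = re.search("N{%d,}" % config.n_run_min, lseq[lo:hi])
    if m:
        ctx.defects.append(
            DefectFlag(
                DefectKind.n_gap,
                where=ctx.to_forward((lo + m.start(), lo + m.end())),
                note=f"run of {m.end() - m.start()} Ns",
            )
        )


def _status_from_defects(defects: list[DefectFlag], n_exons: int) -> GeneStatus:
    kinds = {d.kind for d in defects}
    if kinds & NONFUNCTIONAL_KINDS:
        return GeneStatus.nonfunctional
    if kinds or n_exons < 4:
        return GeneStatus.incomplete
    return GeneStatus.complete


def assemble(
    gdna: SequenceRecord,
    locus: Locus,
    probe: SequenceRecord,
    splice: SpliceConfig | None = None,
    arch: GeneArchitecture | None = None,
    config: AssemblyConfig | None = None,
    gene_id: str = "gene1",
    domain_tail_profile: str | None = None,
) -> tuple[GeneModel, Prepropeptide | None, list[Exon4Candidate]]:
    """Scan-to-model assembly of one locus: exons 1-4, defects, precursor."""
    splice = splice or SpliceConfig()
    arch = arch or GeneArchitecture()
    config = config or AssemblyConfig()
    ctx = map_core_exons(gdna, locus, probe, splice, arch, config)
    candidates: list[Exon4Candidate] = []
    if ctx.exon1 is not None and ctx.exon3 is not None:
        candidates = repair_exon4(ctx, probe, splice, arch, config, domain_tail_profile)
        usable = [c for c in candidates if c.complete]
        if usable:
            ctx.exon4 = usable[0].exon4
        else:
            ctx.defects.append(
                DefectFlag(
                    DefectKind.truncated_scaffold,
                    note="no exon-4 candidate with an in-frame stop",
                )
            )
    # N-gap scan over the whole modelled span (or search window)
    locals_ = [e for e in (ctx.exon1, ctx.exon2, ctx.exon3, ctx.exon4) if e]
    if locals_:
        lo = min(e[0] for e in locals_)
        hi = max(e[1] for e in locals_)
        if ctx.exon4 is None and ctx.exon3 is not None:
            hi = max(hi, ctx.exon3[1] + splice.intron_len_bounds[3][1] + arch.exon4_max_len)
        _scan_n_gaps(ctx, config, (lo, hi))

    model = GeneModel(gene_id=gene_id, source_id=gdna.id, strand=ctx.strand)
    exon_locals = {1: ctx.exon1, 2: ctx.exon2, 3: ctx.exon3, 4: ctx.exon4}
    for idx, loc in exon_locals.items():
        if loc is not None:
            model.exons[idx] = ctx.to_forward(loc)
    # introns between consecutive mapped exons (gene orientation)
    present = [i for i in (1, 2, 3, 4) if exon_locals[i] is not None]
    for a, b in zip(present, present[1:]):
        if b != a + 1:
            continue  # a lesion sits between them; not a real intron
        lo = exon_locals[a][1]
        hi = exon_locals[b][0]
        if hi <= lo:
            continue
        model.introns.append(
            IntronRecord(
                interval=ctx.to_forward((lo, hi)),
                donor5=ctx.lseq[lo : lo + 5],
                acceptor3=ctx.lseq[hi - 3 : hi],
            )
        )

    prepro: Prepropeptide | None = None
    if all(exon_locals[i] is not None for i in (1, 2, 3, 4)):
        prepro = _build_prepropeptide(ctx, exon_locals, config)
        if prepro is not None:
            seq = prepro.sequence
            star = seq.find("*")
            if star != -1 and star < len(seq) - 0:
                # internal stop: the precursor is truncated mid-frame
                exon_idx = prepro.exon_of_residue[star]
                ctx.defects.append(
                    DefectFlag(
                        DefectKind.premature_stop,
                        note=f"stop codon at residue {star + 1} (exon {exon_idx})",
                    )
                )
    model.defects = list(ctx.defects)
    model.status = _status_from_defects(model.defects, len(model.exons))
    model.validate()
    return model, prepro, candidates


def _build_prepropeptide(
    ctx: AssemblyContext,
    exon_locals: dict[int, tuple[int, int] | None],
    config: AssemblyConfig,
) -> Prepropeptide | None:
    lseq = ctx.lseq
    cds = ""
    exon_of_base: list[int] = []
    for i in (1, 2, 3, 4):
        a, b = exon_locals[i]  # type: ignore[misc]
        cds += lseq[a:b]
        exon_of_base.extend([i] * (b - a))
    prot_full = translate(cds, 0)
    if not prot_full:
        return None
    stop = prot_full.find("*")
    last = len(prot_full) - 1
    if stop == last:
        prot = prot_full[:last]  # trim the terminal stop
    else:
        prot = prot_full  # premature stop kept in sequence; flagged upstream
        prot = prot.rstrip("*") if prot.endswith("*") else prot
    n = len(prot)
    exon_of_residue = [exon_of_base[3 * i] for i in range(n)]
    sig_end = min(config.signal_len, max(1, n - 1))
    try:
        first_e4 = exon_of_residue.index(4)
    except ValueError:
        first_e4 = n
    cath_end = min(n, first_e4 + config.cathelin_exon4_residues)
    if cath_end <= sig_end:
        cath_end = min(n, sig_end + 1)
    return Prepropeptide(
        sequence=prot,
        signal_span=(0, sig_end),
        cathelin_span=(sig_end, cath_end),
        exon_of_residue=exon_of_residue,
    )


# ---------------------------------------------------------------------------
# intron statistics


@dataclass
class IntronStat:
    index: int
    length: int
    donor5: str
    acceptor3: str
    canonical_donor: bool
    canonical_acceptor: bool


def intron_stats(model: GeneModel, gdna: SequenceRecord) -> list[IntronStat]:
    """Per-intron length and boundary bases, read directly off the genome.

    Donor/acceptor bases are reported in gene orientation (the strand the
    gene is transcribed from).
    """
    if not model.introns:
        raise CathmineError(f"gene {model.gene_id}: no introns")
    seq = gdna.residues
    out: list[IntronStat] = []
    ordered = sorted(model.introns, key=lambda i: i.interval.start)
    if model.strand == "-":
        ordered = ordered[::-1]
    for k, intron in enumerate(ordered, 1):
        iv = intron.interval
        chunk = seq[iv.start : iv.end]
        if model.strand == "-":
            chunk = reverse_complement(chunk)
        donor5 = chunk[:5]
        acceptor3 = chunk[-3:]
        out.append(
            IntronStat(
                index=k,
                length=len(iv),
                donor5=donor5,
                acceptor3=acceptor3,
                canonical_donor=donor5.startswith("GT"),
                canonical_acceptor=acceptor3.endswith("AG"),
            )
        )
    return out
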