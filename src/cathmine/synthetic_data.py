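"""Seeded synthetic genomic loci with cathelicidin gene architecture.

Generates ground-truthed test genomes: a protein template (by default the
shipped 164-residue probe) is reverse-translated with uniform codon choice
and split into the canonical four-exon layout (variable exon 1, 108 bp
exon 2, 72 bp exon 3, hypervariable exon 4 ending in a stop with a
downstream AATAAA signal). Introns draw GTGAG/GTAAG donors and CAG/TAG
acceptors with realistic length ranges. Gene clusters sit between two
short flanking ORF stubs in the opposite orientation, mimicking the
NDPk / Cdc25 neighbourhood of real cathelicidin loci. Defect directives
inject the lesion classes seen in real assemblies: deleted exon 2,
premature stops, non-AG acceptors, N-gaps and duplicated fourth exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    Alphabet,
    CathmineError,
    CODON_TABLE,
    DefectFlag,
    DefectKind,
    GeneModel,
    GeneStatus,
    Interval,
    IntronRecord,
    SequenceRecord,
    reverse_complement,
    translate,
)
from .gene_assembly import GeneArchitecture, SpliceConfig
from .peptide_derivation import MaturePeptide, derive_mature_peptide

# synonymous codons per residue; stops kept separately
_SYN: dict[str, list[str]] = {}
_STOPS: list[str] = []
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa == "*":
        _STOPS.append(_codon)
    else:
        _SYN.setdefault(_aa, []).append(_codon)

_MARKER_UP = "M" + "NDPKINASE" * 5  # kinase-family stub (geometry only)
_MARKER_DOWN = "M" + "CDCTWENTYFIVE" * 4  # phosphatase-family stub


@dataclass
class DefectDirective:
    """One injected lesion; coordinates are resolved against the gene."""

    kind: str  # delete_exon2 | premature_stop | acceptor_to_GG | insert_Ns | duplicate_exon4
    gene_index: int = 0
    exon: int = 1  # premature_stop target exon
    codon: int = 25  # premature_stop codon index within that exon
    intron: int = 3  # acceptor_to_GG target intron
    n_offset: int = 42  # insert_Ns offset into exon 4
    n_len: int = 200


@dataclass
class SimulationConfig:
    seed: int = 0
    arch: GeneArchitecture = field(default_factory=GeneArchitecture)
    splice: SpliceConfig = field(default_factory=SpliceConfig)
    #: intron length sampling: 1 is triangular(min, mode 603, max); 2-3 uniform
    intron1_range: tuple[int, int, int] = (270, 603, 1200)
    intron2_range: tuple[int, int] = (134, 160)
    intron3_range: tuple[int, int] = (500, 600)
    background_len: int = 100_000
    gc: float = 0.42
    n_genes: int = 1
    cluster: bool = True  # place flanking stubs around the gene block
    defects: list[DefectDirective] = field(default_factory=list)
    mutation_rate: float = 0.0
    template: str | None = None  # protein; default = shipped probe
    genus: str = "Chiromodela"
    epithet: str = "exemplaris"
    donor_probs: tuple[float, ...] = (0.75, 0.25)
    acceptor_probs: tuple[float, ...] = (0.75, 0.25)

    def __post_init__(self) -> None:
        b = self.splice.intron_len_bounds
        for idx, rng in ((1, (self.intron1_range[0], self.intron1_range[2])),
                         (2, self.intron2_range), (3, self.intron3_range)):
            lo, hi = b[idx]
            if not (lo <= rng[0] < rng[1] <= hi):
                raise CathmineError(
                    f"intron {idx} sampling range {rng} outside splice bounds ({lo},{hi})"
                )


@dataclass
class _GeneFeatures:
    """Cluster-local (gene-orientation) layout of one simulated gene."""

    exons: dict[int, list[int]]  # idx -> [start, end), mutable for editing
    introns: dict[int, list[int]]
    cds: str  # pristine coding sequence (before defects)
    e1_len: int
    status: GeneStatus = GeneStatus.complete
    defects: list[DefectFlag] = field(default_factory=list)


@dataclass
class SimulatedLocus:
    gdna: SequenceRecord
    strand: str
    truth: list[GeneModel]
    truth_peptides: list[MaturePeptide]
    flanking: list[Interval]  # two stub ORFs, orientation opposite the genes
    cluster_span: Interval
    config: SimulationConfig


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        try:
            options = _SYN[aa]
        except KeyError:
            raise CathmineError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _make_intron(
    rng: np.random.Generator, length: int, splice: SpliceConfig, cfg: SimulationConfig,
    gc: float,
) -> str:
    donor = splice.preferred_donor5[
        rng.choice(len(splice.preferred_donor5), p=np.array(cfg.donor_probs))
    ]
    acceptor = splice.preferred_acceptor3[
        rng.choice(len(splice.preferred_acceptor3), p=np.array(cfg.acceptor_probs))
    ]
    interior = _random_dna(rng, length - len(donor) - len(acceptor), gc)
    return donor + interior + acceptor


def _stub_orf(rng: np.random.Generator, marker: str) -> str:
    return _reverse_translate(rng, marker)


class _ClusterEditor:
    """Apply sequence edits while shifting all recorded feature coords."""

    def __init__(self, seq: str, genes: list[_GeneFeatures]):
        self.seq = seq
        self.genes = genes

    def _shift(self, pos: int, delta: int) -> None:
        for g in self.genes:
            for coords in list(g.exons.values()) + list(g.introns.values()):
                if coords[0] >= pos:
                    coords[0] += delta
                if coords[1] > pos:
                    coords[1] += delta

    def replace(self, pos: int, old_len: int, new: str) -> None:
        self.seq = self.seq[:pos] + new + self.seq[pos + old_len :]
        delta = len(new) - old_len
        if delta:
            self._shift(pos + old_len, delta)

    def insert(self, pos: int, new: str) -> None:
        self.seq = self.seq[:pos] + new + self.seq[pos:]
        self._shift(pos, len(new))

    def delete(self, pos: int, length: int) -> None:
        self.seq = self.seq[:pos] + self.seq[pos + length :]
        self._shift(pos + length, -length)


def _apply_directive(ed: _ClusterEditor, d: DefectDirective) -> None:
    try:
        g = ed.genes[d.gene_index]
    except IndexError:
        raise CathmineError(f"directive references absent gene {d.gene_index}")
    if d.kind == "delete_exon2":
        if 2 not in g.exons:
            raise CathmineError("exon 2 already absent")
        a, b = g.exons[2]
        ed.delete(a, b - a)
        del g.exons[2]
        g.introns.pop(1, None)  # introns 1+2 fuse around the lesion
        g.introns.pop(2, None)
        g.defects.append(DefectFlag(DefectKind.missing_exon2, note="exon 2 deleted"))
        g.status = GeneStatus.nonfunctional
    elif d.kind == "premature_stop":
        if d.exon not in g.exons:
            raise CathmineError(f"exon {d.exon} absent")
        a, b = g.exons[d.exon]
        cds_before = sum(
            g.exons[i][1] - g.exons[i][0] for i in g.exons if i < d.exon
        )
        off = (3 - cds_before % 3) % 3  # first full codon inside the exon
        pos = a + off + 3 * d.codon
        if pos + 3 > b - 3:
            raise CathmineError("premature-stop codon outside the exon")
        ed.replace(pos, 3, "TAA")
        g.defects.append(
            DefectFlag(DefectKind.premature_stop, note=f"TAA at exon {d.exon} codon {d.codon}")
        )
        g.status = GeneStatus.nonfunctional
    elif d.kind == "acceptor_to_GG":
        if d.intron not in g.introns:
            raise CathmineError(f"intron {d.intron} absent")
        a, b = g.introns[d.intron]
        ed.replace(b - 2, 2, "GG")
        g.defects.append(
            DefectFlag(DefectKind.anomalous_acceptor, note=f"intron {d.intron} ends GG")
        )
        g.status = GeneStatus.nonfunctional
    elif d.kind == "insert_Ns":
        if 4 not in g.exons:
            raise CathmineError("exon 4 absent")
        a, b = g.exons[4]
        off = min(d.n_offset, max(3, (b - a) - 6))
        ed.insert(a + off, "N" * d.n_len)
        g.defects.append(DefectFlag(DefectKind.n_gap, note=f"{d.n_len} Ns in exon 4"))
        if g.status == GeneStatus.complete:
            g.status = GeneStatus.incomplete
    elif d.kind == "duplicate_exon4":
        if 4 not in g.exons:
            raise CathmineError("exon 4 absent")
        a, b = g.exons[4]
        cassette = ed.seq[a - 10 : b + 20]  # carries its own acceptor context
        ed.insert(b + 120, cassette)
    else:
        raise CathmineError(f"unknown defect directive {d.kind!r}")


def simulate(config: SimulationConfig | None = None) -> SimulatedLocus:
    """Generate one seeded locus with machine-readable ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    arch = config.arch
    splice = config.splice

    if config.template is None:
        from .data import load_probe

        template = load_probe().residues
    else:
        template = config.template
    if template[0] != "M":
        raise CathmineError("template protein must start with M")

    core = arch.exon2_len + arch.exon3_len
    genes: list[_GeneFeatures] = []
    parts: list[str] = []
    pos = 0
    for gi in range(config.n_genes):
        cds = _reverse_translate(rng, template)
        e1lo, e1hi = arch.exon1_len_range
        e1_len = int(rng.integers(e1lo, e1hi + 1))
        e4_len = len(cds) - e1_len - core
        if e4_len < 6:
            raise CathmineError("template not divisible into the requested architecture")
        i1 = int(round(rng.triangular(*config.intron1_range)))
        i2 = int(rng.integers(config.intron2_range[0], config.intron2_range[1] + 1))
        i3 = int(rng.integers(config.intron3_range[0], config.intron3_range[1] + 1))
        seg_exons: dict[int, list[int]] = {}
        seg_introns: dict[int, list[int]] = {}
        cursor = pos
        bounds = [e1_len, arch.exon2_len, arch.exon3_len, e4_len]
        cds_cursor = 0
        for idx, (elen, ilen) in enumerate(zip(bounds, [i1, i2, i3, None]), 1):
            parts.append(cds[cds_cursor : cds_cursor + elen])
            seg_exons[idx] = [cursor, cursor + elen]
            cursor += elen
            cds_cursor += elen
            if ilen is not None:
                intron = _make_intron(rng, ilen, splice, config, config.gc)
                parts.append(intron)
                seg_introns[idx] = [cursor, cursor + ilen]
                cursor += ilen
        polya_gap = int(rng.integers(30, 301))
        parts.append(_random_dna(rng, polya_gap, config.gc))
        parts.append("AATAAA")
        cursor += polya_gap + 6
        genes.append(_GeneFeatures(exons=seg_exons, introns=seg_introns, cds=cds, e1_len=e1_len))
        if gi < config.n_genes - 1:
            spacer = int(rng.integers(2000, 4001))
            parts.append(_random_dna(rng, spacer, config.gc))
            cursor += spacer
        pos = cursor

    cluster = "".join(parts)

    # point mutations on the gene body, sparing splice sites, ATG and stops
    if config.mutation_rate > 0:
        protected: set[int] = set()
        for g in genes:
            protected.update(range(g.exons[1][0], g.exons[1][0] + 3))
            protected.update(range(g.exons[4][1] - 3, g.exons[4][1]))
            for a, b in g.introns.values():
                protected.update(range(a, a + 5))
                protected.update(range(b - 3, b))
        arr = list(cluster)
        n_mut = rng.binomial(len(arr), config.mutation_rate)
        sites = rng.choice(len(arr), size=n_mut, replace=False)
        for s in sites:
            if int(s) in protected:
                continue
            alternatives = [c for c in "ACGT" if c != arr[s]]
            arr[s] = alternatives[rng.integers(3)]
        cluster = "".join(arr)

    ed = _ClusterEditor(cluster, genes)
    for directive in config.defects:
        _apply_directive(ed, directive)
    cluster = ed.seq

    strand = "+" if rng.integers(2) == 0 else "-"
    stub_up = _stub_orf(rng, _MARKER_UP)
    stub_down = _stub_orf(rng, _MARKER_DOWN)
    gap1 = int(rng.integers(1000, 2001))
    gap2 = int(rng.integers(1000, 2001))
    cluster_oriented = cluster if strand == "+" else reverse_complement(cluster)
    stub_strand = "-" if strand == "+" else "+"
    stub_up_dna = stub_up if stub_strand == "+" else reverse_complement(stub_up)
    stub_down_dna = stub_down if stub_strand == "+" else reverse_complement(stub_down)
    if config.cluster:
        block = (
            stub_up_dna + _random_dna(rng, gap1, config.gc) + cluster_oriented
            + _random_dna(rng, gap2, config.gc) + stub_down_dna
        )
        cluster_block_off = len(stub_up_dna) + gap1
    else:
        block = cluster_oriented
        cluster_block_off = 0
    if len(block) > config.background_len:
        raise CathmineError(
            f"background_len={config.background_len} too small for the locus "
            f"({len(block)} nt)"
        )
    background = _random_dna(rng, config.background_len, config.gc)
    p = int(rng.integers(0, config.background_len - len(block) + 1))
    gdna_seq = background[:p] + block + background[p + len(block) :]

    Lc = len(cluster)
    c0 = p + cluster_block_off  # forward start of the (oriented) cluster

    def to_forward(a: int, b: int) -> Interval:
        if strand == "+":
            return Interval(c0 + a, c0 + b, "+")
        return Interval(c0 + Lc - b, c0 + Lc - a, "-")

    gdna = SequenceRecord(
        id=f"sim_seed{config.seed}",
        residues=gdna_seq,
        alphabet=Alphabet.dna,
        description=f"sim_seed{config.seed} synthetic cathelicidin locus",
    )

    truth: list[GeneModel] = []
    peptides: list[MaturePeptide] = []
    prior_names: set[str] = set()
    from .data import load_cap18_motif

    motif = load_cap18_motif()
    for gi, g in enumerate(genes):
        model = GeneModel(
            gene_id=f"simgene{gi + 1}", source_id=gdna.id, strand=strand,
            status=g.status, defects=list(g.defects),
        )
        for idx, (a, b) in g.exons.items():
            model.exons[idx] = to_forward(a, b)
        for idx, (a, b) in sorted(g.introns.items()):
            model.introns.append(
                IntronRecord(
                    interval=to_forward(a, b),
                    donor5=cluster[a : a + 5],
                    acceptor3=cluster[b - 3 : b],
                )
            )
        model.validate()
        truth.append(model)
        if g.status == GeneStatus.complete:
            try:
                peptides.append(
                    derive_mature_peptide(
                        exon4_translation_of(g.cds, g.e1_len, arch),
                        config.genus, config.epithet, model.gene_id, motif, prior_names,
                    )
                )
            except CathmineError:
                # no usable valine site / peptide too short for this split
                pass

    flanking: list[Interval] = []
    if config.cluster:
        flanking = [
            Interval(p, p + len(stub_up_dna), stub_strand),
            Interval(p + len(block) - len(stub_down_dna), p + len(block), stub_strand),
        ]

    return SimulatedLocus(
        gdna=gdna,
        strand=strand,
        truth=truth,
        truth_peptides=peptides,
        flanking=flanking,
        cluster_span=Interval(c0, c0 + Lc, strand),
        config=config,
    )


def exon4_translation_of(cds: str, e1_len: int, arch: GeneArchitecture) -> str:
    """Exon-4 residues of a coding sequence (codon assigned to the exon of
    its first base), stop excluded."""
    core = arch.exon2_len + arch.exon3_len
    prot = translate(cds, 0).rstrip("*")
    e4_start_base = e1_len + core
    return "".join(aa for i, aa in enumerate(prot) if 3 * i >= e4_start_base)


def inject_defect(locus: SimulatedLocus, directive: DefectDirective) -> SimulatedLocus:
    """Return the same seeded locus with one more lesion injected."""
    cfg = replace(locus.config, defects=list(locus.config.defects) + [directive])
    return simulate(cfg)
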