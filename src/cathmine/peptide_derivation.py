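"""Mature-peptide derivation, naming, features and structural typing.

Cathelicidin precursors are processed by neutrophil elastase, whose
preferred cleavage site is the first valine of the exon-4 translation: the
mature antimicrobial peptide is everything after that valine. Peptides are
named Genus-initial + two epithet letters + first two residues + length
(e.g. Pme_PR31), and classified into eight structural types from CAP18
status, proline/arginine richness, cysteine count and a secondary-structure
string (heuristic propensity-based, or user-supplied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core_io import CathmineError

# ---------------------------------------------------------------------------
# cleavage and naming


class NoCleavageSiteError(CathmineError):
    """Raised when the exon-4 translation contains no valine."""


@dataclass(frozen=True)
class CleavageResult:
    peptide: str  # residues after the first valine
    propiece: str  # everything up to and including the valine


def cleave_at_first_valine(exon4_translation: str) -> CleavageResult:
    """Elastase rule: the mature peptide starts after the first V."""
    seq = exon4_translation.rstrip("*")
    pos = seq.find("V")
    if pos == -1:
        raise NoCleavageSiteError("no valine in exon-4 translation")
    return CleavageResult(peptide=seq[pos + 1 :], propiece=seq[: pos + 1])


def name_peptide(
    genus: str, epithet: str, peptide: str, prior_names: set[str] | list[str] = ()
) -> str:
    """Genus initial + two epithet letters + '_' + first two residues + length.

    A repeated name gets '-n' appended, n counting occurrences from 2.
    """
    if not (genus.isalpha() and epithet.isalpha()):
        raise CathmineError("genus and epithet must be alphabetic")
    if len(peptide) < 2:
        raise CathmineError("peptide must have at least 2 residues")
    base = genus[0].upper() + epithet[:2].lower() + "_" + peptide[:2].upper() + str(len(peptide))
    if base not in prior_names:
        return base
    n = 2
    while f"{base}-{n}" in prior_names:
        n += 1
    return f"{base}-{n}"


def cysteine_spacings(seq: str, conserved_quartet: bool = False) -> list[int]:
    """Residue counts strictly between consecutive cysteines.

    With ``conserved_quartet`` only the four C-terminal-most cysteines are
    used, excluding e.g. the signal-peptide cysteine of a full precursor.
    """
    positions = [i for i, c in enumerate(seq) if c == "C"]
    if conserved_quartet:
        if len(positions) < 4:
            raise CathmineError(
                f"conserved quartet requested but only {len(positions)} cysteines"
            )
        positions = positions[-4:]
    return [b - a - 1 for a, b in zip(positions, positions[1:])]


# ---------------------------------------------------------------------------
# CAP18 motif

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_ANCHOR_SET = set("ILFV")


@dataclass
class Cap18Motif:
    """Position-weight profile of the CAP18 (LPS-binding, helix-prone) region.

    ``anchor_positions`` are columns that must hold a bulky hydrophobic
    residue (I/L/F/V) for a confident call; thresholds are fractions of the
    profile's self-consensus score.
    """

    profile: np.ndarray  # (ncols, 20) log-odds weights
    anchor_positions: tuple[int, ...]
    theta_present: float
    theta_similar: float
    consensus: str

    def __post_init__(self) -> None:
        if not self.theta_present > self.theta_similar:
            raise CathmineError("require theta_present > theta_similar")
        if any(p >= self.profile.shape[0] for p in self.anchor_positions):
            raise CathmineError("anchor position outside profile")

    @classmethod
    def from_sequences(
        cls,
        seqs: list[str],
        pseudocount: float = 0.5,
        present_frac: float = 0.60,
        similar_frac: float = 0.40,
    ) -> "Cap18Motif":
        """Build a log-odds profile from equal-length ungapped sequences.

        Columns where every sequence holds I/L/F/V become anchor columns.
        Thresholds default to fixed fractions of the maximal (consensus)
        score; ``similar_frac`` is set so that composition-preserving
        shuffles of the consensus almost never reach it.
        """
        if len(set(map(len, seqs))) != 1:
            raise CathmineError("motif sequences must be aligned to equal length")
        ncols = len(seqs[0])
        counts = np.full((ncols, 20), pseudocount)
        for s in seqs:
            for j, a in enumerate(s):
                if a in _AA_INDEX:
                    counts[j, _AA_INDEX[a]] += 1.0
        freqs = counts / counts.sum(axis=1, keepdims=True)
        profile = np.log2(freqs / 0.05)
        anchors = tuple(
            j for j in range(ncols) if all(s[j] in _ANCHOR_SET for s in seqs)
        )
        consensus = "".join(_AA[int(profile[j].argmax())] for j in range(ncols))
        max_score = float(profile.max(axis=1).sum())
        return cls(
            profile=profile,
            anchor_positions=anchors,
            theta_present=present_frac * max_score,
            theta_similar=similar_frac * max_score,
            consensus=consensus,
        )


class Cap18Status(str, Enum):
    present = "present"
    similar = "similar"
    absent = "absent"


def cap18_score(
    peptide: str, motif: Cap18Motif, max_overhang_frac: float = 0.25
) -> tuple[float, Cap18Status]:
    """Best ungapped profile placement on the peptide, plus the anchor rule.

    present: all anchor columns sit on I/L/F/V and score >= theta_present;
    similar: score >= theta_similar; absent otherwise.
    """
    ncols = motif.profile.shape[0]
    overhang = int(round(ncols * max_overhang_frac))
    if ncols > len(peptide) + 2 * overhang:
        raise CathmineError("peptide too short for the CAP18 profile")
    best_score = -np.inf
    best_anchors = False
    for off in range(-overhang, len(peptide) - ncols + overhang + 1):
        score = 0.0
        anchors_ok = True
        n_cols_used = 0
        for j in range(ncols):
            k = off + j
            if 0 <= k < len(peptide):
                aa = peptide[k]
                if aa in _AA_INDEX:
                    score += float(motif.profile[j, _AA_INDEX[aa]])
                n_cols_used += 1
                if j in motif.anchor_positions and aa not in _ANCHOR_SET:
                    anchors_ok = False
            elif j in motif.anchor_positions:
                anchors_ok = False
        if n_cols_used == 0:
            continue
        if score > best_score or (score == best_score and anchors_ok and not best_anchors):
            best_score = score
            best_anchors = anchors_ok
    if best_anchors and best_score >= motif.theta_present:
        return best_score, Cap18Status.present
    if best_score >= motif.theta_similar:
        return best_score, Cap18Status.similar
    return best_score, Cap18Status.absent


# ---------------------------------------------------------------------------
# secondary-structure heuristic (Chou-Fasman-style propensities)

_HELIX = {
    "E": 1.51, "M": 1.45, "A": 1.42, "L": 1.21, "K": 1.16, "F": 1.13, "Q": 1.11,
    "W": 1.08, "I": 1.08, "V": 1.06, "D": 1.01, "H": 1.00, "R": 0.98, "T": 0.83,
    "S": 0.77, "C": 0.70, "Y": 0.69, "N": 0.67, "P": 0.57, "G": 0.57, "X": 1.00,
}
_SHEET = {
    "V": 1.70, "I": 1.60, "Y": 1.47, "F": 1.38, "W": 1.37, "L": 1.30, "C": 1.19,
    "T": 1.19, "Q": 1.10, "M": 1.05, "R": 0.93, "N": 0.89, "H": 0.87, "A": 0.83,
    "S": 0.75, "G": 0.75, "K": 0.74, "P": 0.55, "D": 0.54, "E": 0.37, "X": 1.00,
}
_TURN = {
    "N": 1.56, "G": 1.56, "P": 1.52, "D": 1.46, "S": 1.43, "C": 1.19, "Y": 1.14,
    "K": 1.01, "Q": 0.98, "T": 0.96, "W": 0.96, "R": 0.95, "H": 0.95, "E": 0.74,
    "A": 0.66, "M": 0.60, "F": 0.60, "L": 0.59, "V": 0.50, "I": 0.47, "X": 1.00,
}

#: minimal run lengths for a segment to count
_MIN_RUN = {"H": 4, "E": 3, "T": 2}


def secondary_structure(
    peptide: str, window: int = 5, override: str | None = None
) -> str:
    """Per-residue H/E/T/C string from windowed propensity averages.

    A user-supplied string (e.g. from a structure model) overrides the
    heuristic verbatim. Runs shorter than the minimal segment length
    (4 for H, 3 for E, 2 for T) are demoted to coil.
    """
    if override is not None:
        if len(override) != len(peptide) or set(override) - set("HETC"):
            raise CathmineError("override must match peptide length over {H,E,T,C}")
        return override
    n = len(peptide)
    if n < 4:
        raise CathmineError("peptide too short for structure assignment")
    half = window // 2
    raw = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        chunk = peptide[lo:hi]
        pa = sum(_HELIX.get(c, 1.0) for c in chunk) / len(chunk)
        pb = sum(_SHEET.get(c, 1.0) for c in chunk) / len(chunk)
        pt = sum(_TURN.get(c, 1.0) for c in chunk) / len(chunk)
        best, state = max((pa, "H"), (pb, "E"), (pt, "T"))
        raw.append(state if best >= 1.0 else "C")
    # demote runs below the minimal segment length
    out = []
    i = 0
    while i < n:
        j = i
        while j < n and raw[j] == raw[i]:
            j += 1
        state = raw[i]
        if state in _MIN_RUN and (j - i) < _MIN_RUN[state]:
            out.extend("C" * (j - i))
        else:
            out.extend(state * (j - i))
        i = j
    return "".join(out)


def _count_segments(ss: str, state: str) -> int:
    count = 0
    prev = None
    for c in ss:
        if c == state and prev != state:
            count += 1
        prev = c
    return count


# ---------------------------------------------------------------------------
# features and classification


@dataclass
class PeptideFeatures:
    length: int
    cys_positions: list[int]
    cys_spacings: list[int]
    pro_fraction: float
    arg_fraction: float
    ss_string: str
    helix_segments: int
    strand_segments: int
    turn_segments: int


def peptide_features(peptide: str, ss_string: str | None = None) -> PeptideFeatures:
    ss = secondary_structure(peptide, override=ss_string) if len(peptide) >= 4 else "C" * len(peptide)
    cys = [i for i, c in enumerate(peptide) if c == "C"]
    n = len(peptide)
    return PeptideFeatures(
        length=n,
        cys_positions=cys,
        cys_spacings=[b - a - 1 for a, b in zip(cys, cys[1:])],
        pro_fraction=peptide.count("P") / n,
        arg_fraction=peptide.count("R") / n,
        ss_string=ss,
        helix_segments=_count_segments(ss, "H"),
        strand_segments=_count_segments(ss, "E"),
        turn_segments=_count_segments(ss, "T"),
    )


class PeptideType(str, Enum):
    T1 = "T1"  # CAP18, single alpha-helix
    T2 = "T2"  # CAP18, two helices joined by a turn
    T3 = "T3"  # no CAP18, single alpha-helix
    T4 = "T4"  # helix packed against a beta-strand
    T5 = "T5"  # no CAP18, two helices joined by a turn
    T6 = "T6"  # proline- and arginine-rich extended peptide
    T7 = "T7"  # arginine-rich, proline-poor extended peptide
    T8 = "T8"  # two-cysteine (potential disulphide / dipeptide) peptide
    unclassified = "unclassified"


@dataclass
class TypeThresholds:
    pro_rich: float = 0.15
    arg_rich: float = 0.20
    pro_poor: float = 0.05


def classify(
    features: PeptideFeatures,
    cap18: Cap18Status,
    thresholds: TypeThresholds | None = None,
) -> PeptideType:
    """Decision list over the eight structural types; first match wins.

    CAP18 'similar' routes with 'present' for the structural branches but is
    reported separately in output tables.
    """
    th = thresholds or TypeThresholds()
    if len(features.cys_positions) == 2:
        return PeptideType.T8
    if features.pro_fraction >= th.pro_rich and features.arg_fraction >= th.arg_rich:
        return PeptideType.T6
    if features.arg_fraction >= th.arg_rich and features.pro_fraction < th.pro_poor:
        return PeptideType.T7
    cap = cap18 in (Cap18Status.present, Cap18Status.similar)
    h, e, t = features.helix_segments, features.strand_segments, features.turn_segments
    if h == 1 and e == 0:
        return PeptideType.T1 if cap else PeptideType.T3
    if h == 2 and t >= 1 and e == 0:
        return PeptideType.T2 if cap else PeptideType.T5
    if h >= 1 and e >= 1:
        return PeptideType.T4
    return PeptideType.unclassified


# ---------------------------------------------------------------------------
# assembled peptide record


@dataclass
class MaturePeptide:
    name: str
    sequence: str
    genus: str
    epithet: str
    source_gene: str
    propiece: str
    features: PeptideFeatures
    cap18: Cap18Status
    cap18_score: float
    ptype: PeptideType
    from_defective_gene: bool = False  # psi flag for nonfunctional sources

    def __post_init__(self) -> None:
        if not self.sequence or "*" in self.sequence:
            raise CathmineError("mature peptide must be non-empty and stop-free")


def derive_mature_peptide(
    exon4_translation: str,
    genus: str,
    epithet: str,
    source_gene: str,
    motif: Cap18Motif,
    prior_names: set[str],
    ss_string: str | None = None,
    from_defective_gene: bool = False,
    thresholds: TypeThresholds | None = None,
) -> MaturePeptide:
    """Cleave, name, featurize and type one exon-4 translation."""
    cut = cleave_at_first_valine(exon4_translation)
    if len(cut.peptide) < 2:
        raise CathmineError("cleaved peptide shorter than 2 residues")
    name = name_peptide(genus, epithet, cut.peptide, prior_names)
    prior_names.add(name)
    feats = peptide_features(cut.peptide, ss_string)
    try:
        score, status = cap18_score(cut.peptide, motif)
    except CathmineError:
        score, status = float("-inf"), Cap18Status.absent
    return MaturePeptide(
        name=name,
        sequence=cut.peptide,
        genus=genus,
        epithet=epithet,
        source_gene=source_gene,
        propiece=cut.propiece,
        features=feats,
        cap18=status,
        cap18_score=score,
        ptype=classify(feats, status, thresholds),
        from_defective_gene=from_defective_gene,
    )
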