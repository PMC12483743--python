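"""Package data: the cathelicidin search probe and the CAP18 motif set.

The probe is the 164-residue consensus of four bat cathelicidin precursors
used for translated genome search. The CAP18 motif file holds a small,
hand-built *synthetic* set of aligned CAP18-region exemplars (user-
replaceable); the motif is data, not code.
"""

from __future__ import annotations

from importlib import resources

from ..core_io import SequenceRecord, read_fasta
from ..peptide_derivation import Cap18Motif


def _data_path(name: str):
    return resources.files(__package__) / name


def load_probe() -> SequenceRecord:
    """The 164-residue cathelicidin consensus probe."""
    with resources.as_file(_data_path("probe.fasta")) as p:
        return read_fasta(p)[0]


def load_cap18_motif() -> Cap18Motif:
    """Default CAP18 profile built from the shipped synthetic exemplars."""
    with resources.as_file(_data_path("cap18_synthetic.fasta")) as p:
        seqs = [r.residues for r in read_fasta(p)]
    return Cap18Motif.from_sequences(seqs)
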