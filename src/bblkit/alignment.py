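"""Codon-aware alignments, translation, identity statistics and THCAS reference numbering.

The in-memory container is :class:`MSA`, a validated list of equal-length
aligned nucleotide (or protein) sequences.  Sequence numbering throughout the
package follows the full-length THCAS preprotein convention: residue 1 is the
initiator methionine, and alignment columns where the reference carries a gap
are labelled by their anchor residue plus a letter suffix (e.g. ``358a``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, AlphabetError, FrameError, InputError, MappingError

NT_ALPHABET = frozenset("ACGTN-")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X-")

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


@dataclass
class MSA:
    """A multiple sequence alignment with unique ids and equal-length rows.

    Parameters
    ----------
    records : list of (id, sequence) tuples
        Aligned sequences over ``{A,C,G,T,N,-}`` (or amino acids when
        ``alphabet='protein'``).
    codon_frame : int
        0-based offset of the first codon position; the packaged pipelines
        always use codon-aware alignments with frame 0.
    """

    records: list[tuple[str, str]]
    codon_frame: int = 0
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        allowed = NT_ALPHABET if self.alphabet == "nucleotide" else AA_ALPHABET
        for rid, seq in self.records:
            bad = set(seq.upper()) - allowed
            if bad:
                raise AlphabetError(f"{rid}: illegal characters {sorted(bad)}")
        self.records = [(rid, seq.upper()) for rid, seq in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise InputError(f"id {rid!r} not in alignment")

    def __contains__(self, rid: str) -> bool:
        return any(r == rid for r, _ in self.records)

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.records)

    def to_protein(self) -> "MSA":
        """Translate a codon-aware nucleotide alignment column-block-wise."""
        if self.alphabet != "nucleotide":
            raise InputError("alignment is already protein")
        recs = [(rid, translate(seq)) for rid, seq in self.records]
        return MSA(recs, alphabet="protein")

    def degap(self, rid: str) -> str:
        return self[rid].replace("-", "")


def read_alignment(path: str | Path, alphabet: str = "nucleotide") -> MSA:
    """Read an aligned FASTA file into a validated :class:`MSA`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return MSA(records, alphabet=alphabet)


def write_fasta(records: Iterable[tuple[str, str]] | MSA, path: str | Path) -> None:
    if isinstance(records, MSA):
        records = records.records
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seq_records, str(Path(path)), "fasta-2line")


def pad_frameshift(seq: str, indel_sites: Sequence[int]) -> str:
    """Restore the reading frame of a frameshifted pseudogene by inserting ``N``.

    ``indel_sites`` are 0-based offsets *in the returned sequence* at which a
    single ``N`` is placed (pass an offset twice for a 2-nt deletion).  This is
    the standard pre-processing that lets pseudogenes enter a codon-aware
    alignment: downstream of each pad the original 3' frame is preserved.
    """
    out = list(seq)
    for pos in sorted(indel_sites):
        if pos < 0 or pos > len(out):
            raise InputError(f"indel offset {pos} out of range for length-{len(out)} sequence")
        out.insert(pos, "N")
    padded = "".join(out)
    if len(padded) % 3 != 0:
        raise FrameError(
            f"padded length {len(padded)} is not a multiple of 3; check indel sites"
        )
    return padded


def translate_codon(codon: str) -> str:
    """Translate one codon; all-gap -> '-', partial gap or N-containing -> 'X'."""
    codon = codon.upper()
    if codon == "---":
        return "-"
    if "-" in codon:
        warnings.warn(f"mixed gap/nucleotide codon {codon!r} translated as X", stacklevel=2)
        return "X"
    if "N" in codon:
        return "X"
    try:
        return _CODON_TABLE[codon]
    except KeyError as exc:  # pragma: no cover - alphabet is validated upstream
        raise AlphabetError(f"untranslatable codon {codon!r}") from exc


def translate(seq: str | MSA) -> str | MSA:
    """Translate a coding sequence (or every row of a codon alignment)."""
    if isinstance(seq, MSA):
        return seq.to_protein()
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


@dataclass
class IdentityResult:
    """Pairwise identity with substitution and indel-event accounting.

    ``percent`` uses only columns where both sequences carry a residue; each
    maximal contiguous gap run in one sequence counts as a single indel event.
    """

    percent: float
    matches: int
    substitutions: int
    indel_events: int
    indel_lengths: list[int] = field(default_factory=list)

    @property
    def aligned_pairs(self) -> int:
        return self.matches + self.substitutions


def pairwise_identity(a: str, b: str, align: bool = False) -> IdentityResult:
    """Identity between two sequences, pre-aligned unless ``align=True``.

    Gapped columns are excluded from the denominator; terminal and internal
    gaps are treated identically (one event per maximal run).
    """
    if not a or not b:
        raise InputError("empty sequence")
    if align:
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="global",
            match_score=2,
            mismatch_score=-1,
            open_gap_score=-5,
            extend_gap_score=-0.5,
        )
        aln = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
        a, b = str(aln[0]), str(aln[1])
    if len(a) != len(b):
        raise AlignmentError("sequences differ in aligned length; pass align=True")
    matches = subs = 0
    indel_lengths: list[int] = []
    run = 0
    for ca, cb in zip(a, b):
        gap_a, gap_b = ca == "-", cb == "-"
        if gap_a and gap_b:
            continue
        if gap_a or gap_b:
            run += 1
            continue
        if run:
            indel_lengths.append(run)
            run = 0
        if ca == cb:
            matches += 1
        else:
            subs += 1
    if run:
        indel_lengths.append(run)
    denom = matches + subs
    if denom == 0:
        raise InputError("no aligned residue pairs between the two sequences")
    return IdentityResult(
        percent=100.0 * matches / denom,
        matches=matches,
        substitutions=subs,
        indel_events=len(indel_lengths),
        indel_lengths=indel_lengths,
    )


@dataclass
class Partition:
    """Assignment of alignment columns to site classes.

    The default mirrors the standard codon partition used for protein-coding
    nucleotide data: class 0 = codon positions 1+2, class 1 = codon position 3.
    """

    classes: list[list[int]]

    @classmethod
    def codon_positions(cls, length: int, scheme: str = "12_3", frame: int = 0) -> "Partition":
        if scheme == "none":
            return cls([list(range(length))])
        if length % 3 != 0:
            raise FrameError(f"alignment length {length} not a multiple of 3")
        pos = [(i - frame) % 3 for i in range(length)]
        if scheme == "12_3":
            classes = [
                [i for i in range(length) if pos[i] in (0, 1)],
                [i for i in range(length) if pos[i] == 2],
            ]
        elif scheme == "1_2_3":
            classes = [[i for i in range(length) if pos[i] == k] for k in range(3)]
        elif scheme == "none":
            classes = [list(range(length))]
        else:
            raise InputError(f"unknown partition scheme {scheme!r}")
        return cls(classes)

    @classmethod
    def single(cls, length: int) -> "Partition":
        return cls([list(range(length))])

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for cols in self.classes:
            overlap = seen & set(cols)
            if overlap:
                raise InputError(f"columns assigned to multiple classes: {sorted(overlap)[:5]}")
            seen |= set(cols)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class ReferenceMap:
    """Bijection between reference residues and alignment residue columns.

    ``column_to_ref`` maps 0-based residue columns to 1-based reference residue
    numbers; columns gapped in the reference get ``labels`` of the form
    ``<anchor><letter>`` (insertions relative to the reference).
    """

    ref_id: str
    column_to_ref: dict[int, int]
    labels: dict[int, str]

    def __post_init__(self) -> None:
        nums = [self.column_to_ref[c] for c in sorted(self.column_to_ref)]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise MappingError("reference residue numbers are not strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.column_to_ref)

    def label_of(self, column: int) -> str:
        """Human-readable position label for a residue column."""
        if column in self.column_to_ref:
            return str(self.column_to_ref[column])
        if column in self.labels:
            return self.labels[column]
        raise MappingError(f"column {column} not mapped")

    def column_of(self, residue: int) -> int:
        for col, num in self.column_to_ref.items():
            if num == residue:
                return col
        raise MappingError(f"reference residue {residue} not present in map")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column_index\tref_residue\tlabel\n")
            for col in range(max(list(self.column_to_ref) + list(self.labels)) + 1):
                if col in self.column_to_ref:
                    fh.write(f"{col}\t{self.column_to_ref[col]}\t{self.column_to_ref[col]}\n")
                elif col in self.labels:
                    fh.write(f"{col}\t\t{self.labels[col]}\n")


def build_reference_map(msa: MSA, ref_id: str) -> ReferenceMap:
    """Number residue columns by their homologous position in the reference.

    Accepts either a protein alignment or a codon-aware nucleotide alignment
    (which is translated first).  Columns where the reference has a residue get
    that residue's 1-based number; reference-gap columns are labelled by the
    preceding residue plus ``a``, ``b``, ...
    """
    if ref_id not in msa:
        raise InputError(f"reference id {ref_id!r} not in alignment")
    prot = msa.to_protein() if msa.alphabet == "nucleotide" else msa
    ref_seq = prot[ref_id]
    column_to_ref: dict[int, int] = {}
    labels: dict[int, str] = {}
    residue = 0
    suffix = 0
    for col, aa in enumerate(ref_seq):
        if aa == "-":
            labels[col] = f"{residue}{chr(ord('a') + suffix)}"
            suffix += 1
        else:
            residue += 1
            suffix = 0
            column_to_ref[col] = residue
    return ReferenceMap(ref_id=ref_id, column_to_ref=column_to_ref, labels=labels)
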