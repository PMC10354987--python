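"""Core value types shared by every pipeline stage.

All coordinates held in these objects are 0-based, half-open. Conversion to
the 1-based inclusive convention of GenBank/GFF3 happens only at the format
boundary (see :mod:`mitoloop.io`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: one-letter amino-acid code used to shorten tRNA names (trnF = tRNA-Phe)
_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_ROMAN = {"I": "1", "II": "2", "III": "3"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_bases(raw: str) -> str:
    """Uppercase, map U->T, and validate the alphabet."""
    bases = raw.upper().replace("U", "T")
    if not bases:
        raise ValueError("empty sequence")
    if re.search(r"[^ACGTN]", bases):
        bad = sorted(set(re.findall(r"[^ACGTN]", bases)))
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return bases


def normalize_gene_name(name: str) -> str:
    """Map the common synonyms of mitochondrial gene names onto one namespace.

    Gene sets are compared across annotations (reference vs. each candidate
    contig), which only works if ``COI``, ``CO1`` and ``COX1`` collapse to a
    single key, and ``tRNA-Phe`` to ``trnF``. Unrecognised names are returned
    stripped but otherwise untouched.
    """
    raw = name.strip()
    up = raw.upper().replace(" ", "")
    # tRNAs: tRNA-Phe, trnF, TRN-F, trnL2 ...
    m = re.fullmatch(r"TRNA?[-_]?([A-Z]{3})(\d?)", up)
    if m and m.group(1) in _AA3_TO_1:
        return "trn" + _AA3_TO_1[m.group(1)] + m.group(2)
    m = re.fullmatch(r"TRN([A-Z])(\d?)", up)
    if m:
        return "trn" + m.group(1) + m.group(2)
    # cytochrome oxidase subunits
    m = re.fullmatch(r"(?:MT-)?CO(?:X)?(I{1,3}|[123])", up)
    if m:
        sub = _ROMAN.get(m.group(1), m.group(1))
        return "COX" + sub
    # NADH dehydrogenase subunits
    m = re.fullmatch(r"(?:MT-)?N(?:AD|D)(\d)(L?)", up)
    if m:
        return "NAD" + m.group(1) + m.group(2)
    if up in {"COB", "CYB", "CYTB", "MT-CYB"}:
        return "CYTB"
    m = re.fullmatch(r"(?:MT-)?ATP(?:ASE)?(6|8)", up)
    if m:
        return "ATP" + m.group(1)
    if up in {"RRNS", "12S", "12SRRNA", "S-RRNA", "RNS", "SSU", "SRRNA"}:
        return "rrnS"
    if up in {"RRNL", "16S", "16SRRNA", "L-RRNA", "RNL", "LSU", "LRRNA"}:
        return "rrnL"
    return raw


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (read, contig, or reference)."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        self.bases = normalize_bases(self.bases)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, new_id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(new_id or self.id, revcomp(self.bases), self.description)


FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "gene", "other")

#: qualifier key marking a feature whose span wraps the sequence origin;
#: such features keep start < end by letting end exceed the sequence length.
ORIGIN_SPANNING = "origin_spanning"


@dataclass
class FeatureRecord:
    """A located, stranded gene feature on one sequence."""

    seq_id: str
    kind: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive; may exceed seq length iff origin-spanning
    strand: str
    name: str
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def spans_origin(self) -> bool:
        return bool(self.qualifiers.get(ORIGIN_SPANNING))

    def extract(self, bases: str) -> str:
        """Feature sequence in reading orientation (strand-aware, wrap-aware)."""
        n = len(bases)
        if self.end <= n:
            sub = bases[self.start:self.end]
        else:
            if not self.spans_origin:
                raise ValueError(f"feature {self.name} exceeds sequence length")
            sub = bases[self.start:] + bases[: self.end - n]
        return sub if self.strand == "+" else revcomp(sub)


@dataclass
class AnnotationSet:
    """An ordered feature list for one sequence plus its genetic code."""

    seq_id: str
    features: list[FeatureRecord]
    genetic_code_id: int = 5

    def __post_init__(self) -> None:
        for f in self.features:
            if f.seq_id != self.seq_id:
                raise ValueError(
                    f"feature {f.name} references {f.seq_id!r}, not {self.seq_id!r}"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.name))

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_kind(self, *kinds: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind in kinds]

    def by_name(self, name: str) -> list[FeatureRecord]:
        want = normalize_gene_name(name)
        return [f for f in self.features if normalize_gene_name(f.name) == want]

    def gene_names(self) -> list[str]:
        return [normalize_gene_name(f.name) for f in self.features]
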