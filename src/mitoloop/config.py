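"""User-settable thresholds for every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


TAXON_MODES = ("default", "plant", "fungi")


@dataclass
class PipelineConfig:
    """All tunables in one place.

    ``max_read_len`` defaults to the reference length at run time (``None``
    here): mapped reads longer than the reference are treated as likely
    NUMT-derived and dropped. ``p_coverage`` is the minimum percent of a
    contig's length that must be covered by reference matches for the contig
    to survive filtering. ``circular_size`` is the minimum terminal-redundancy
    length (strict >) for a contig to be called circular.
    """

    # read recruitment
    max_read_len: int | None = None        # bp; None -> reference length
    recruit_min_identity: float = 0.7      # cross-species reference, permissive
    seed_k: int = 15
    min_chain_seeds: int = 3

    # contig filtering
    p_coverage: float = 50.0               # percent of contig length

    # circularization
    circular_size: int = 220               # bp, strict >
    circular_min_identity: float = 0.99

    # annotation
    genetic_code_id: int = 5
    transfer_min_identity: float = 0.6
    transfer_min_identity_short: float = 0.8   # features < 100 bp (tRNAs)
    transfer_min_ref_coverage: float = 0.7

    # assembler
    min_overlap: int = 1000                # bp suffix-prefix overlap
    min_overlap_identity: float = 0.99
    min_read_identity: float = 0.97        # read-vs-consensus floor
    min_structural_indel: int = 50         # bp; larger indel defers the read
    min_deferred_reads: int = 3            # second-round trigger

    # finalization
    size_similarity: tuple = (0.8, 1.2)    # x reference length
    cov_mapq_min: int = 0

    # orchestration
    taxon_mode: str = "default"
    threads: int = 1

    def __post_init__(self) -> None:
        if self.max_read_len is not None and self.max_read_len <= 0:
            raise ValueError("max_read_len must be positive")
        if not 0 < self.p_coverage < 100:
            raise ValueError("p_coverage must be in (0, 100)")
        if self.circular_size < 0:
            raise ValueError("circular_size must be >= 0")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.taxon_mode not in TAXON_MODES:
            raise ValueError(f"taxon_mode must be one of {TAXON_MODES}")

    def resolved_max_read_len(self, reference_length: int) -> int:
        return self.max_read_len if self.max_read_len is not None else reference_length

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_similarity"] = list(self.size_similarity)
        return d
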