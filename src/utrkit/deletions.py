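"""3'UTR deletion-allele modelling and motif-content deltas.

An allelic series of engineered 3'UTR deletions (e.g. spr5–spr10 in the
*mex-3* UTR) is represented as named 1-based inclusive intervals on a parent
UTR.  Applying a deletion splices the interval out; the motif-content delta
classifies every wild-type catalog match as removed (overlapping the
deletion), retained upstream (coordinates unchanged) or retained downstream
(shifted left by the deletion length), and reports any match newly created
across the deletion junction separately.

The 1-based inclusive convention is fixed by the allele arithmetic it must
reproduce: interval 328–517 is a 190 bp deletion, 28–515 is 488 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import MotifConsensus, MotifMatch, count_catalog_matches, normalize_sequence

__all__ = [
    "CoordinateError",
    "UTRRecord",
    "DeletionAllele",
    "ClassifiedMatch",
    "MotifDelta",
    "deletion_length",
    "apply_deletion",
    "motif_delta",
]


class CoordinateError(ValueError):
    """An interval does not fit its parent sequence."""


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR sequence (normalized RNA alphabet).

    ``annotations`` is free-form metadata (e.g. annotated polyadenylation
    sites); it is carried, never computed on.
    """

    utr_id: str
    seq: str
    annotations: dict = field(default_factory=dict, compare=False)

    @property
    def length(self) -> int:
        return len(self.seq)

    @classmethod
    def from_raw(cls, utr_id: str, raw_seq: str, **annotations) -> "UTRRecord":
        return cls(utr_id=utr_id, seq=normalize_sequence(raw_seq), annotations=annotations)


@dataclass(frozen=True)
class DeletionAllele:
    """A named deletion: 1-based inclusive interval removed from a parent UTR."""

    name: str
    start: int
    end: int
    parent_id: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"allele {self.name!r}: invalid interval {self.start}-{self.end}"
            )


def deletion_length(allele: DeletionAllele) -> int:
    """Number of deleted bases: end − start + 1 (inclusive interval)."""
    return allele.end - allele.start + 1


def apply_deletion(utr: UTRRecord, allele: DeletionAllele) -> UTRRecord:
    """Splice the allele's interval out of the UTR.

    The mutant id is ``<parent>_<allele>``; its length is the parent length
    minus the deletion length.
    """
    if allele.end > utr.length:
        raise CoordinateError(
            f"allele {allele.name!r}: interval {allele.start}-{allele.end} "
            f"exceeds UTR {utr.utr_id!r} length {utr.length}"
        )
    mutant_seq = utr.seq[: allele.start - 1] + utr.seq[allele.end :]
    return UTRRecord(utr_id=f"{utr.utr_id}_{allele.name}", seq=mutant_seq)


@dataclass(frozen=True)
class ClassifiedMatch:
    """A wild-type catalog match with its fate under a deletion.

    ``status`` is one of removed / retained_up / retained_down / junction;
    mutant coordinates are None for removed matches and wild-type
    coordinates are None for junction-gained ones.
    """

    motif: str
    status: str
    wt_start: int | None
    wt_end: int | None
    mut_start: int | None
    mut_end: int | None
    spacer_len: int


@dataclass(frozen=True)
class MotifDelta:
    """Motif-content change between a wild-type UTR and a deletion mutant."""

    allele: str
    removed: tuple[ClassifiedMatch, ...]
    retained_upstream: tuple[ClassifiedMatch, ...]
    retained_downstream: tuple[ClassifiedMatch, ...]
    junction_gained: tuple[ClassifiedMatch, ...]
    counts_before: dict[str, int]
    counts_after: dict[str, int]

    @property
    def retained(self) -> tuple[ClassifiedMatch, ...]:
        return self.retained_upstream + self.retained_downstream

    def all_rows(self) -> list[ClassifiedMatch]:
        return [
            *self.removed,
            *self.retained_upstream,
            *self.retained_downstream,
            *self.junction_gained,
        ]


def motif_delta(
    utr: UTRRecord,
    allele: DeletionAllele,
    catalog: list[MotifConsensus],
) -> MotifDelta:
    """Classify every wild-type catalog match under a deletion.

    A match overlapping the deleted interval at all — including matches
    merely straddling a boundary, whose recognised bases are disrupted — is
    ``removed``.  Matches wholly upstream keep their coordinates; matches
    wholly downstream shift left by the deletion length.  The mutant is then
    rescanned: any match absent from the retained set arose across the new
    junction and is reported as ``junction`` (not counted as retained).
    """
    shift = deletion_length(allele)
    mutant = apply_deletion(utr, allele)
    wt_matches = count_catalog_matches(utr.seq, catalog)
    mut_matches = count_catalog_matches(mutant.seq, catalog)

    removed: list[ClassifiedMatch] = []
    up: list[ClassifiedMatch] = []
    down: list[ClassifiedMatch] = []
    retained_keys: set[tuple[str, int, int, int]] = set()
    for motif_name, hits in wt_matches.items():
        for hit in hits:
            if hit.end < allele.start:
                up.append(
                    ClassifiedMatch(
                        motif_name, "retained_up", hit.start, hit.end,
                        hit.start, hit.end, hit.spacer_len,
                    )
                )
                retained_keys.add((motif_name, hit.start, hit.end, hit.spacer_len))
            elif hit.start > allele.end:
                down.append(
                    ClassifiedMatch(
                        motif_name, "retained_down", hit.start, hit.end,
                        hit.start - shift, hit.end - shift, hit.spacer_len,
                    )
                )
                retained_keys.add(
                    (motif_name, hit.start - shift, hit.end - shift, hit.spacer_len)
                )
            else:
                removed.append(
                    ClassifiedMatch(
                        motif_name, "removed", hit.start, hit.end,
                        None, None, hit.spacer_len,
                    )
                )

    junction = [
        ClassifiedMatch(motif_name, "junction", None, None,
                        hit.start, hit.end, hit.spacer_len)
        for motif_name, hits in mut_matches.items()
        for hit in hits
        if (motif_name, hit.start, hit.end, hit.spacer_len) not in retained_keys
    ]

    return MotifDelta(
        allele=allele.name,
        removed=tuple(removed),
        retained_upstream=tuple(up),
        retained_downstream=tuple(down),
        junction_gained=tuple(junction),
        counts_before={name: len(hits) for name, hits in wt_matches.items()},
        counts_after={name: len(hits) for name, hits in mut_matches.items()},
    )
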