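"""Bipartite RNA-binding-protein motif models, ΔΔG scoring and sequence scanning.

Many germline RBPs (MEX-3 being the motivating case) recognise a *bipartite*
element: two short half-sites separated by a variable-length spacer whose
bases are not read out.  The MEX-3 recognition element (MRE) is
``(A/G/U)(G/U)AG`` then 0–8 arbitrary bases then ``U(U/A/C)UA``; each KH
domain binds one half-site.

Candidate sites are scored under an additive independent-position model: a
penalty matrix assigns each recognised position a free-energy penalty
ΔΔG°(position, base) ≥ 0 relative to the best-bound base, and a site's total
ΔΔG° is the sum over recognised positions (spacer bases contribute nothing).
The relative dissociation constant follows the standard Boltzmann relation

    K_rel = exp(ΔΔG° / RT),      affinity = 1 / K_rel ∈ (0, 1],

so a consensus-perfect site has affinity 1 and heavily penalised sites
approach 0.  Per-position affinity tracks ("wiggle" profiles) place each
reported site's affinity at its start coordinate by default.

All coordinates are 1-based with inclusive ends; sequences are RNA-alphabet
uppercase (T accepted on input, mapped to U).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BASES",
    "MalformedSequenceError",
    "MotifParseError",
    "UnsupportedMotifError",
    "MotifConsensus",
    "PenaltyMatrix",
    "ScanConfig",
    "BindingSite",
    "AffinityProfile",
    "MotifMatch",
    "MEX3_CONSENSUS_PATTERN",
    "mex3_consensus",
    "normalize_sequence",
    "parse_consensus",
    "consensus_penalty_matrix",
    "site_ddg",
    "krel_from_ddg",
    "affinity_from_ddg",
    "scan",
    "affinity_profile",
    "count_catalog_matches",
    "catalog_counts",
]

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: The MEX-3 recognition element: two half-sites, 0-8 nt spacer.
MEX3_CONSENSUS_PATTERN = "(A/G/U)(G/U)AGN{0-8}U(U/A/C)UA"


class MalformedSequenceError(ValueError):
    """A sequence contains a character outside the DNA/RNA alphabet."""


class MotifParseError(ValueError):
    """A degenerate-motif string could not be parsed."""


class UnsupportedMotifError(MotifParseError):
    """Motif structure outside the supported bipartite/single-half-site forms."""


def normalize_sequence(raw: str) -> str:
    """Uppercase RNA normalization: strip whitespace, map T→U.

    Raises :class:`MalformedSequenceError` naming the 1-based offending
    position for any character outside ``ACGTU`` (either case).
    """
    stripped = "".join(raw.split())
    out = []
    for pos, ch in enumerate(stripped, start=1):
        up = ch.upper()
        if up == "T":
            up = "U"
        if up not in _BASE_INDEX:
            raise MalformedSequenceError(
                f"invalid character {ch!r} at position {pos}"
            )
        out.append(up)
    return "".join(out)


@dataclass(frozen=True)
class MotifConsensus:
    """A bipartite degenerate motif: left half-site, spacer range, right half-site.

    Each half-site position is a nonempty set of allowed RNA bases.  The right
    half-site may be empty, which encodes a plain (non-bipartite) degenerate
    motif such as the OMA-1/2-associated ``UA(U/A)``; the spacer is then
    irrelevant and fixed at 0.
    """

    name: str
    left: tuple[frozenset[str], ...]
    spacer_min: int
    spacer_max: int
    right: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if not self.left:
            raise MotifParseError(f"motif {self.name!r}: empty left half-site")
        for group in (*self.left, *self.right):
            if not group or not group <= frozenset(BASES):
                raise MotifParseError(
                    f"motif {self.name!r}: allowed-base set {set(group)!r} "
                    f"is not a nonempty subset of {{A,C,G,U}}"
                )
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise MotifParseError(
                f"motif {self.name!r}: invalid spacer range "
                f"{self.spacer_min}-{self.spacer_max}"
            )
        if not self.right and (self.spacer_min, self.spacer_max) != (0, 0):
            raise UnsupportedMotifError(
                f"motif {self.name!r}: spacer without a right half-site"
            )

    @property
    def positions(self) -> tuple[frozenset[str], ...]:
        """Recognized positions in matrix row order (left then right)."""
        return self.left + self.right

    @property
    def n_positions(self) -> int:
        return len(self.left) + len(self.right)

    def site_length(self, spacer_len: int) -> int:
        return len(self.left) + spacer_len + len(self.right)


_TOKEN_RE = re.compile(
    r"\(([ACGUTacgut/]+)\)"      # parenthesized group (A/G/U)
    r"|N\{(\d+)-(\d+)\}"          # spacer token N{min-max}
    r"|([ACGUTacgut])"            # bare base
)


def _parse_group(text: str, motif: str) -> frozenset[str]:
    bases = set()
    for token in text.split("/"):
        token = token.strip().upper().replace("T", "U")
        if len(token) != 1 or token not in _BASE_INDEX:
            raise MotifParseError(f"motif {motif!r}: bad base token {token!r}")
        bases.add(token)
    return frozenset(bases)


def parse_consensus(
    text: str, name: str | None = None, *, require_spacer: bool = True
) -> MotifConsensus:
    """Parse a degenerate-motif string like ``(A/G/U)(G/U)AGN{0-8}U(U/A/C)UA``.

    Bare bases become singleton sets; ``(X/Y/..)`` becomes an allowed-base
    set; exactly one ``N{min-max}`` token splits left from right half-site.
    With ``require_spacer=False`` a spacer-free pattern is accepted and
    encoded as a left-only motif with a fixed spacer of 0 (used for catalog
    motifs such as ``UA(U/A)``).
    """
    motif_name = name if name is not None else text
    compact = "".join(text.split())
    if not compact:
        raise MotifParseError("empty motif string")
    halves: list[list[frozenset[str]]] = [[]]
    spacer: tuple[int, int] | None = None
    pos = 0
    while pos < len(compact):
        m = _TOKEN_RE.match(compact, pos)
        if m is None:
            raise MotifParseError(
                f"motif {motif_name!r}: unparseable at {compact[pos:]!r}"
            )
        group, smin, smax, bare = m.groups()
        if smin is not None:
            if spacer is not None:
                raise UnsupportedMotifError(
                    f"motif {motif_name!r}: multiple spacer tokens"
                )
            spacer = (int(smin), int(smax))
            halves.append([])
        elif group is not None:
            halves[-1].append(_parse_group(group, motif_name))
        else:
            halves[-1].append(_parse_group(bare, motif_name))
        pos = m.end()

    if spacer is None:
        if require_spacer:
            raise UnsupportedMotifError(
                f"motif {motif_name!r}: no N{{min-max}} spacer token"
            )
        return MotifConsensus(motif_name, tuple(halves[0]), 0, 0, ())
    left, right = halves
    if not left or not right:
        raise MotifParseError(f"motif {motif_name!r}: empty half-site")
    return MotifConsensus(motif_name, tuple(left), spacer[0], spacer[1], tuple(right))


def mex3_consensus() -> MotifConsensus:
    """The default MEX-3 MRE consensus instance."""
    return parse_consensus(MEX3_CONSENSUS_PATTERN, name="MEX-3")


@dataclass(frozen=True)
class PenaltyMatrix:
    """Per-position, per-base ΔΔG° penalties relative to the best-bound sequence.

    ``penalties`` has one row per recognized position (left half-site rows
    first, then right; spacer positions carry no row) and one column per base
    in ``ACGU`` order.  Every row is finite, non-negative and contains at
    least one exact zero (the best base).
    """

    penalties: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.penalties, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("penalty matrix must be (n_positions, 4)")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("penalties must be finite and >= 0")
        if np.any(arr.min(axis=1) != 0):
            raise ValueError("every row needs at least one zero-penalty base")
        object.__setattr__(self, "penalties", arr)

    @property
    def n_positions(self) -> int:
        return self.penalties.shape[0]

    def row_map(self, row: int) -> dict[str, float]:
        return {b: float(self.penalties[row, i]) for i, b in enumerate(BASES)}


def consensus_penalty_matrix(
    consensus: MotifConsensus, default_penalty: float = 1.0
) -> PenaltyMatrix:
    """Build a matrix from a consensus alone: allowed bases score 0,
    disallowed bases score ``default_penalty`` (> 0, in RT units)."""
    if not default_penalty > 0:
        raise ValueError("default_penalty must be > 0")
    arr = np.full((consensus.n_positions, 4), float(default_penalty))
    for row, allowed in enumerate(consensus.positions):
        for base in allowed:
            arr[row, _BASE_INDEX[base]] = 0.0
    return PenaltyMatrix(arr)


@dataclass(frozen=True)
class ScanConfig:
    """Scanner configuration.

    RT sets the energy scale of the ΔΔG↔K_rel conversion (dimensionless 1.0
    by default; 0.593 kcal/mol at 25 °C if the matrix is in kcal/mol).
    Sites with ΔΔG above ``max_ddg`` (default 3·RT, affinity ≈ 0.05) are not
    reported.  ``profile_rule`` places a site's affinity at its start
    position ("start") or over its whole footprint ("footprint");
    ``tie_rule`` breaks equal-ΔΔG spacer ties ("shortest_spacer" default).
    """

    RT: float = 1.0
    max_ddg: float | None = None
    profile_rule: str = "start"
    tie_rule: str = "shortest_spacer"

    def __post_init__(self) -> None:
        if not self.RT > 0:
            raise ValueError("RT must be > 0")
        if self.max_ddg is not None and self.max_ddg < 0:
            raise ValueError("max_ddg must be >= 0")
        if self.profile_rule not in ("start", "footprint"):
            raise ValueError(f"unknown profile_rule {self.profile_rule!r}")
        if self.tie_rule not in ("shortest_spacer", "longest_spacer"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")

    @property
    def effective_max_ddg(self) -> float:
        return 3.0 * self.RT if self.max_ddg is None else self.max_ddg


@dataclass(frozen=True)
class BindingSite:
    """A scored candidate site (1-based inclusive coordinates)."""

    utr_id: str
    start: int
    end: int
    spacer_len: int
    ddg: float
    krel: float
    affinity: float
    perfect: bool


@dataclass(frozen=True)
class AffinityProfile:
    """Per-position 1/K_rel track over a UTR; positions with no site are 0."""

    utr_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("profile values must be 1-D")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("profile values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def length(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class MotifMatch:
    """An exact degenerate match of a catalog motif (1-based inclusive)."""

    motif: str
    start: int
    end: int
    spacer_len: int


def site_ddg(matrix: PenaltyMatrix, left_seq: str, right_seq: str) -> float:
    """Additive ΔΔG° of a candidate site: sum of per-position penalties of
    the observed recognised bases (spacer excluded; independence assumed)."""
    n = len(left_seq) + len(right_seq)
    if n != matrix.n_positions:
        raise ValueError(
            f"half-site lengths ({len(left_seq)}+{len(right_seq)}) do not "
            f"match matrix rows ({matrix.n_positions})"
        )
    total = 0.0
    for row, base in enumerate(left_seq + right_seq):
        try:
            total += float(matrix.penalties[row, _BASE_INDEX[base]])
        except KeyError:
            raise MalformedSequenceError(f"invalid base {base!r}") from None
    return total


def krel_from_ddg(ddg: float, RT: float = 1.0) -> float:
    """Relative Kd: K_rel = exp(ΔΔG°/RT); 1 at ΔΔG = 0, → ∞ as ΔΔG grows."""
    if ddg < 0:
        raise ValueError("ddg must be >= 0")
    if not RT > 0:
        raise ValueError("RT must be > 0")
    return math.exp(ddg / RT)


def affinity_from_ddg(ddg: float, RT: float = 1.0) -> float:
    """1/K_rel ∈ (0, 1]; 1 = binding equivalent to the best-bound sequence."""
    return 1.0 / krel_from_ddg(ddg, RT)


def _seq_indices(seq: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_BASE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq)
        )
    except KeyError as exc:
        raise MalformedSequenceError(
            f"invalid base {exc.args[0]!r}; normalize the sequence first"
        ) from None


def _half_site_tracks(
    idx: np.ndarray,
    pen: np.ndarray,
    allowed: np.ndarray,
    row_offset: int,
    width: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window penalty sums and all-allowed flags for one half-site.

    Returns arrays of length ``n - width + 1``: element ``i`` covers the
    window starting at 0-based position ``i``.
    """
    n = idx.size
    m = n - width + 1
    if m <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    sums = np.zeros(m)
    ok = np.ones(m, dtype=bool)
    for offset in range(width):
        col = idx[offset : offset + m]
        sums += pen[row_offset + offset, col]
        ok &= allowed[row_offset + offset, col]
    return sums, ok


def _allowed_mask(consensus: MotifConsensus) -> np.ndarray:
    mask = np.zeros((consensus.n_positions, 4), dtype=bool)
    for row, bases in enumerate(consensus.positions):
        for b in bases:
            mask[row, _BASE_INDEX[b]] = True
    return mask


def scan(
    seq: str,
    consensus: MotifConsensus,
    matrix: PenaltyMatrix | None = None,
    config: ScanConfig | None = None,
    utr_id: str = "seq",
) -> list[BindingSite]:
    """Score every candidate site; report the best per start position.

    For every start and every admissible spacer length that fits, the
    candidate's ΔΔG is the penalty sum over recognised positions.  Per start
    only the minimum-ΔΔG candidate is emitted (ties broken per
    ``config.tie_rule``, default shortest spacer) and only if its ΔΔG does
    not exceed ``config.max_ddg``.  Output is sorted by start.  ``perfect``
    is true iff every recognised base is consensus-allowed.
    """
    config = config or ScanConfig()
    matrix = matrix if matrix is not None else consensus_penalty_matrix(consensus)
    if matrix.n_positions != consensus.n_positions:
        raise ValueError("matrix rows do not match consensus positions")
    n = len(seq)
    L, R = len(consensus.left), len(consensus.right)
    if n < consensus.site_length(consensus.spacer_min):
        return []
    idx = _seq_indices(seq)
    allowed = _allowed_mask(consensus)
    left_sum, left_ok = _half_site_tracks(idx, matrix.penalties, allowed, 0, L)
    if R:
        right_sum, right_ok = _half_site_tracks(idx, matrix.penalties, allowed, L, R)
    else:
        right_sum = np.zeros(n + 1)
        right_ok = np.ones(n + 1, dtype=bool)

    spacers = range(consensus.spacer_min, consensus.spacer_max + 1)
    if config.tie_rule == "longest_spacer":
        spacers = reversed(list(spacers))

    n_starts = n - consensus.site_length(consensus.spacer_min) + 1
    best_ddg = np.full(n_starts, np.inf)
    best_spacer = np.full(n_starts, -1, dtype=int)
    best_perfect = np.zeros(n_starts, dtype=bool)
    for s in spacers:
        m = n - consensus.site_length(s) + 1
        if m <= 0:
            continue
        if R:
            ddg = left_sum[:m] + right_sum[L + s : L + s + m]
            perf = left_ok[:m] & right_ok[L + s : L + s + m]
        else:
            ddg = left_sum[:m].copy()
            perf = left_ok[:m].copy()
        better = ddg < best_ddg[:m]
        best_spacer[:m][better] = s
        best_perfect[:m][better] = perf[better]
        best_ddg[:m][better] = ddg[better]

    max_ddg = config.effective_max_ddg
    sites = []
    for i in np.nonzero(best_ddg <= max_ddg)[0]:
        s = int(best_spacer[i])
        ddg = float(best_ddg[i])
        start = int(i) + 1
        sites.append(
            BindingSite(
                utr_id=utr_id,
                start=start,
                end=start + consensus.site_length(s) - 1,
                spacer_len=s,
                ddg=ddg,
                krel=krel_from_ddg(ddg, config.RT),
                affinity=affinity_from_ddg(ddg, config.RT),
                perfect=bool(best_perfect[i]),
            )
        )
    return sites


def affinity_profile(
    sites: Iterable[BindingSite], length: int, rule: str = "start"
) -> AffinityProfile:
    """Collapse sites to a per-position affinity track.

    Default rule "start": position i carries the maximum affinity over sites
    starting at i.  Rule "footprint": every position a site covers carries
    the running maximum instead.  Uncovered positions are 0.
    """
    sites = list(sites)
    values = np.zeros(length)
    utr_id = sites[0].utr_id if sites else "seq"
    for site in sites:
        if not (1 <= site.start <= site.end <= length):
            raise ValueError(
                f"site [{site.start},{site.end}] outside [1,{length}]"
            )
        if rule == "start":
            i = site.start - 1
            values[i] = max(values[i], site.affinity)
        elif rule == "footprint":
            lo, hi = site.start - 1, site.end
            values[lo:hi] = np.maximum(values[lo:hi], site.affinity)
        else:
            raise ValueError(f"unknown profile rule {rule!r}")
    return AffinityProfile(utr_id=utr_id, values=values)


def count_catalog_matches(
    seq: str, catalog: Sequence[MotifConsensus]
) -> dict[str, list[MotifMatch]]:
    """All exact degenerate matches per catalog motif.

    Every (start, spacer) combination whose recognised bases are all allowed
    is reported — no per-start reduction, overlaps included.  Matches are
    sorted by (start, spacer).
    """
    idx = _seq_indices(seq)
    n = idx.size
    out: dict[str, list[MotifMatch]] = {}
    for motif in catalog:
        allowed = _allowed_mask(motif)
        L, R = len(motif.left), len(motif.right)
        matches: list[MotifMatch] = []
        if n >= motif.site_length(motif.spacer_min):
            ones = np.ones((motif.n_positions, 4))  # penalties unused here
            _, left_ok = _half_site_tracks(idx, ones, allowed, 0, L)
            if R:
                _, right_ok = _half_site_tracks(idx, ones, allowed, L, R)
            else:
                right_ok = np.ones(n + 1, dtype=bool)
            for s in range(motif.spacer_min, motif.spacer_max + 1):
                m = n - motif.site_length(s) + 1
                if m <= 0:
                    continue
                if R:
                    hit = left_ok[:m] & right_ok[L + s : L + s + m]
                else:
                    hit = left_ok[:m]
                for i in np.nonzero(hit)[0]:
                    start = int(i) + 1
                    matches.append(
                        MotifMatch(
                            motif=motif.name,
                            start=start,
                            end=start + motif.site_length(s) - 1,
                            spacer_len=s,
                        )
                    )
        matches.sort(key=lambda m: (m.start, m.spacer_len))
        out[motif.name] = matches
    return out


def catalog_counts(matches: Mapping[str, list[MotifMatch]]) -> dict[str, int]:
    """Per-motif match counts from a :func:`count_catalog_matches` result."""
    return {name: len(hits) for name, hits in matches.items()}
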