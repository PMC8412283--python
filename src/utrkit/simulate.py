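"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all pure functions of their spec (including the seed):

* :func:`synth_utr` — UTR-like random sequences with bipartite motif sites
  planted at known coordinates.  The background is resampled (rejection)
  until the only perfect consensus matches in the emitted sequence are the
  planted ones, so ground truth is exact by construction.
* :func:`synth_profiles` — germline line profiles: a three-segment
  piecewise-linear axial baseline (distal-high → pachytene-low →
  oocyte-rising) plus i.i.d. Gaussian pixel noise; treated animals receive
  an additive de-repression shift confined to chosen bins, using exactly the
  bin geometry of :func:`utrkit.profiles.bin_profile`.
* :func:`synth_broods` — per-animal brood counts from a negative binomial
  (worm brood assays are overdispersed relative to Poisson), with a
  location shift for the treated condition.

Defaults emulate the motivating system: a 689-nt UTR, 20 bins, n = 15
animals per imaging group, control broods near 250 progeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deletions import UTRRecord
from .motifs import (
    BASES,
    BindingSite,
    MotifConsensus,
    count_catalog_matches,
    mex3_consensus,
)
from .profiles import LineProfile, bin_pixel_slices

__all__ = [
    "SpecError",
    "CapacityError",
    "SynthUTRSpec",
    "SynthProfileSpec",
    "SynthBroodSpec",
    "synth_utr",
    "synth_profiles",
    "synth_broods",
]


class SpecError(ValueError):
    """A synthetic-data spec is internally inconsistent."""


class CapacityError(RuntimeError):
    """Rejection sampling could not satisfy the spec within the attempt bound."""


@dataclass(frozen=True)
class SynthUTRSpec:
    """Planted-motif UTR spec.

    ``planted`` holds (position, spacer_len, site) triples; ``site`` is the
    literal RNA sequence to write or the string ``"perfect"`` to sample a
    consensus-perfect site.  ``background`` is the A/C/G/U composition.
    """

    length: int = 689
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted: tuple[tuple[int, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise SpecError("length must be >= 0")
        comp = np.asarray(self.background, dtype=float)
        if comp.shape != (4,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
            raise SpecError("background must be 4 non-negative fractions summing to 1")


def _planted_interval(
    pos: int, spacer: int, consensus: MotifConsensus
) -> tuple[int, int]:
    return pos, pos + consensus.site_length(spacer) - 1


def _sample_perfect_site(
    consensus: MotifConsensus,
    spacer: int,
    rng: np.random.Generator,
    background: np.ndarray,
) -> str:
    left = [rng.choice(sorted(g)) for g in consensus.left]
    spacer_bases = rng.choice(list(BASES), size=spacer, p=background)
    right = [rng.choice(sorted(g)) for g in consensus.right]
    return "".join(left) + "".join(spacer_bases) + "".join(right)


def synth_utr(
    spec: SynthUTRSpec,
    consensus: MotifConsensus | None = None,
    max_attempts: int = 200,
) -> tuple[UTRRecord, list[BindingSite]]:
    """Emit a UTR whose perfect consensus matches are exactly the planted ones.

    Each attempt draws a fresh background (and fresh "perfect" site samples),
    overwrites the planted windows, and enumerates all perfect matches; the
    sequence is accepted only when that enumeration equals the planted set.
    Raises :class:`CapacityError` after ``max_attempts`` rejections, which
    signals that the spec (length × composition) admits too many accidental
    sites to de-novo-clean within the bound.
    """
    consensus = consensus or mex3_consensus()
    background = np.asarray(spec.background, dtype=float)
    intervals: list[tuple[int, int]] = []
    for pos, spacer, site in spec.planted:
        if not (consensus.spacer_min <= spacer <= consensus.spacer_max):
            raise SpecError(f"spacer {spacer} outside consensus range")
        start, end = _planted_interval(pos, spacer, consensus)
        if not (1 <= start and end <= spec.length):
            raise SpecError(f"planted site [{start},{end}] outside UTR")
        if site != "perfect" and len(site) != consensus.site_length(spacer):
            raise SpecError(
                f"planted sequence length {len(site)} != site length "
                f"{consensus.site_length(spacer)}"
            )
        intervals.append((start, end))
    intervals.sort()
    for (_, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise SpecError("planted sites overlap")

    planted_keys = set()
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list(BASES))
    for _ in range(max_attempts):
        seq_arr = rng.choice(bases, size=spec.length, p=background)
        planted_keys = set()
        for pos, spacer, site in spec.planted:
            text = (
                _sample_perfect_site(consensus, spacer, rng, background)
                if site == "perfect"
                else site
            )
            start, end = _planted_interval(pos, spacer, consensus)
            seq_arr[start - 1 : end] = list(text)
            planted_keys.add((start, end, spacer))
        seq = "".join(seq_arr)
        found = {
            (m.start, m.end, m.spacer_len)
            for m in count_catalog_matches(seq, [consensus])[consensus.name]
        }
        if found == planted_keys:
            record = UTRRecord(utr_id=f"synthUTR_seed{spec.seed}", seq=seq)
            truth = [
                BindingSite(
                    utr_id=record.utr_id, start=s, end=e, spacer_len=sp,
                    ddg=0.0, krel=1.0, affinity=1.0, perfect=True,
                )
                for s, e, sp in sorted(planted_keys)
            ]
            return record, truth
    raise CapacityError(
        f"no accidental-match-free sequence found in {max_attempts} attempts "
        f"(length {spec.length})"
    )


#: Axial baseline nodes as (fraction along the axis, intensity): a
#: three-segment distal-high → pachytene-low → oocyte-rising shape.
DEFAULT_BASELINE: tuple[tuple[float, float], ...] = (
    (0.0, 100.0),
    (0.35, 20.0),
    (0.70, 30.0),
    (1.0, 120.0),
)


@dataclass(frozen=True)
class SynthProfileSpec:
    """Germline line-profile spec: baseline + Gaussian noise + optional
    bin-restricted de-repression of ``effect_size`` × ``noise_sd``."""

    n_animals: int = 15
    pixels: int = 400
    n_bins: int = 20
    baseline: tuple[tuple[float, float], ...] = DEFAULT_BASELINE
    effect_bins: tuple[int, ...] = ()
    effect_size: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise SpecError("noise_sd must be > 0")
        if self.pixels < self.n_bins or self.n_bins < 1:
            raise SpecError("need pixels >= n_bins >= 1")
        if any(not (1 <= b <= self.n_bins) for b in self.effect_bins):
            raise SpecError("effect_bins must lie in [1, n_bins]")
        if self.n_animals < 2:
            raise SpecError("need >= 2 animals per condition")


def _baseline_curve(spec: SynthProfileSpec) -> np.ndarray:
    nodes = np.asarray(spec.baseline, dtype=float)
    frac = np.linspace(0.0, 1.0, spec.pixels)
    return np.interp(frac, nodes[:, 0], nodes[:, 1])


def synth_profiles(
    spec: SynthProfileSpec,
) -> tuple[dict[str, list[LineProfile]], tuple[int, ...]]:
    """Control and treated line-profile groups plus the true effect bins.

    Control animals are baseline + N(0, noise_sd) per pixel; treated animals
    additionally receive ``effect_size × noise_sd`` on every pixel of the
    effect bins (bin geometry identical to the analysis binning).  Negative
    noise excursions are clipped at 0, as fluorescence cannot go negative.
    """
    rng = np.random.default_rng(spec.seed)
    base = _baseline_curve(spec)
    effect = np.zeros(spec.pixels)
    slices = bin_pixel_slices(spec.pixels, spec.n_bins)
    for b in spec.effect_bins:
        effect[slices[b - 1]] = spec.effect_size * spec.noise_sd
    groups: dict[str, list[LineProfile]] = {"control": [], "treated": []}
    for condition, shift in (("control", 0.0), ("treated", 1.0)):
        for i in range(spec.n_animals):
            noise = rng.normal(0.0, spec.noise_sd, size=spec.pixels)
            intensities = np.clip(base + shift * effect + noise, 0.0, None)
            groups[condition].append(
                LineProfile(
                    animal_id=f"{condition}_{i + 1}",
                    condition=condition,
                    intensities=intensities,
                )
            )
    return groups, tuple(spec.effect_bins)


@dataclass(frozen=True)
class SynthBroodSpec:
    """Brood-count spec: negative-binomial counts, treated mean shifted down."""

    n: int = 30
    mean: float = 250.0
    dispersion: float = 10.0
    shift: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.dispersion > 0):
            raise SpecError("mean and dispersion must be > 0")
        if self.shift >= self.mean:
            raise SpecError("shift must be < mean (treated mean must stay > 0)")
        if self.n < 1 or self.n_replicates < 1:
            raise SpecError("n and n_replicates must be >= 1")


def _nb_counts(
    mean: float, dispersion: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    # numpy parameterization: successes k ~ NB(n=size, p); mean = n(1-p)/p
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def synth_broods(spec: SynthBroodSpec):
    """Control/treated brood datasets plus the true location shift."""
    from .fecundity import BroodDataset

    rng = np.random.default_rng(spec.seed)
    reps = (np.arange(spec.n) % spec.n_replicates) + 1
    control = BroodDataset(
        condition="control",
        counts=_nb_counts(spec.mean, spec.dispersion, spec.n, rng),
        replicates=reps,
    )
    treated = BroodDataset(
        condition="treated",
        counts=_nb_counts(spec.mean - spec.shift, spec.dispersion, spec.n, rng),
        replicates=reps.copy(),
    )
    return control, treated, spec.shift
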