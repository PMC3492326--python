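"""Signal-to-noise quantification and competitor-based candidate calling.

The competition assay probes two copies of a proteome microarray with a
fluorescent lectin, one with an excess of free glycan competitor and one
without.  Per spot, the signal-to-noise ratio (SNR) is the foreground
median divided by the local background median; per protein it is the
arithmetic mean over replicate spots.  The Calling Score is the
fold-suppression SNR(−)/SNR(+): glycan-dependent binding collapses under
competition (high score) while nonspecific lectin binding persists
(score ≈ 1).  Candidates are proteins passing both inclusive cutoffs,
by default SNR(−) ≥ 3 and Calling Score ≥ 2.5.

All internal comparisons use full floating-point precision; rounding
(half-up, 2 decimals, matching how the published table prints values)
happens only in the reporting layer (:func:`round_half_up`).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterator, Mapping, Sequence

from .errors import (
    ConditionError,
    EmptyInputError,
    GlycocallError,
    IntegrityError,
    UndefinedRatioError,
)
from .microarray_io import ArrayScan, Condition, SpotRecord

__all__ = [
    "CallThresholds",
    "ProteinSNR",
    "SnrTable",
    "CompetitionResult",
    "PairScores",
    "spot_snr",
    "protein_snr",
    "calling_score",
    "call_candidates",
    "score_pair",
    "round_half_up",
]

#: Flag raised on a result whose SNR(+) is exactly zero: the score is
#: undefined (infinite fold-suppression), treated as passing the score
#: cutoff but made visible because a zero background-corrected signal is
#: more likely a quantification artifact than perfect competition.
COMPLETE_SUPPRESSION = "complete_suppression"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed score tables.

    Python's builtin ``round`` is banker's rounding; published tables
    round 0.005 up, so reporting goes through :class:`decimal.Decimal`.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True, slots=True)
class CallThresholds:
    """The two inclusive cutoffs of the dual candidate filter."""

    snr_minus_min: float = 3.0
    calling_score_min: float = 2.5

    def __post_init__(self) -> None:
        if self.snr_minus_min < 0 or self.calling_score_min < 0:
            raise IntegrityError("thresholds must be non-negative")


@dataclass(frozen=True, slots=True)
class ProteinSNR:
    """Replicate-averaged SNR of one protein under one condition."""

    protein_id: str
    condition: Condition
    snr: float
    n_spots_used: int
    n_spots_excluded: int = 0


@dataclass(frozen=True)
class SnrTable:
    """Per-protein SNRs of one scan plus the exclusion bookkeeping.

    Iterating yields :class:`ProteinSNR` records.  ``excluded`` lists
    proteins with zero usable spots (all replicates flagged or with zero
    background) — reported, never silently dropped.  ``control_snrs``
    carries positive-control SNRs for QC display; controls never enter
    candidate calling.
    """

    values: tuple[ProteinSNR, ...]
    excluded: tuple[str, ...] = ()
    control_snrs: Mapping[str, float] = field(default_factory=dict)

    def __iter__(self) -> Iterator[ProteinSNR]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, ProteinSNR]:
        return {p.protein_id: p for p in self.values}


@dataclass(frozen=True, slots=True)
class CompetitionResult:
    """Joined per-protein record of the two-array comparison.

    ``calling_score`` is ``None`` (undefined) when ``snr_plus`` is zero;
    such results carry the ``complete_suppression`` flag.
    """

    protein_id: str
    snr_minus: float
    snr_plus: float
    calling_score: float | None
    is_candidate: bool
    flags: tuple[str, ...] = ()
    annotation: str | None = None


@dataclass(frozen=True)
class PairScores:
    """Sequence of :class:`CompetitionResult` plus join/exclusion lists."""

    results: tuple[CompetitionResult, ...]
    unpaired: tuple[str, ...] = ()
    excluded: tuple[str, ...] = ()

    def __iter__(self) -> Iterator[CompetitionResult]:
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i: int) -> CompetitionResult:
        return self.results[i]

    def candidates(self) -> tuple[CompetitionResult, ...]:
        return tuple(r for r in self.results if r.is_candidate)


def spot_snr(spot: SpotRecord) -> float:
    """Per-spot SNR: foreground median over local background median.

    Raises :class:`UndefinedRatioError` when the background median is
    zero; the aggregation policy excludes such spots rather than
    assigning them infinite SNR.
    """
    if spot.bg_median == 0:
        raise UndefinedRatioError(
            f"spot ({spot.block}, {spot.row}, {spot.column}) "
            f"[{spot.protein_id!r}] has zero background median"
        )
    return spot.fg_median / spot.bg_median


def _usable(spot: SpotRecord) -> bool:
    return spot.flag >= 0 and spot.bg_median > 0


def protein_snr(scan: ArrayScan) -> SnrTable:
    """Replicate-averaged SNR per protein for one scan.

    Sample spots are grouped by protein identifier; spots flagged bad
    (flag < 0) or with zero background median are excluded from the
    mean.  Control and buffer spots never enter the sample table;
    control SNRs are summarized separately for QC.  Proteins whose spots
    were all excluded are listed in ``excluded``.
    """
    if len(scan) == 0:
        raise EmptyInputError(f"scan {scan.scan_id!r} has no spots")
    sample = scan.sample_spots()
    if not sample:
        raise EmptyInputError(f"scan {scan.scan_id!r} has no sample spots")

    by_protein: dict[str, list[SpotRecord]] = defaultdict(list)
    for spot in sample:
        by_protein[spot.protein_id].append(spot)

    values: list[ProteinSNR] = []
    dropped: list[str] = []
    for pid, spots in by_protein.items():
        usable = [s for s in spots if _usable(s)]
        if not usable:
            dropped.append(pid)
            continue
        mean_snr = sum(spot_snr(s) for s in usable) / len(usable)
        values.append(
            ProteinSNR(
                protein_id=pid,
                condition=scan.condition,
                snr=mean_snr,
                n_spots_used=len(usable),
                n_spots_excluded=len(spots) - len(usable),
            )
        )

    controls: dict[str, list[float]] = defaultdict(list)
    for spot in scan.spots:
        if spot.spot_kind.value == "positive_control" and _usable(spot):
            controls[spot.protein_id].append(spot_snr(spot))
    control_means = {pid: sum(v) / len(v) for pid, v in controls.items()}

    return SnrTable(
        values=tuple(values),
        excluded=tuple(sorted(dropped)),
        control_snrs=control_means,
    )


def calling_score(snr_minus: float, snr_plus: float) -> float | None:
    """Fold-suppression score SNR(−)/SNR(+); ``None`` when SNR(+) = 0."""
    if snr_minus < 0 or snr_plus < 0:
        raise GlycocallError(
            f"SNR values must be non-negative, got ({snr_minus}, {snr_plus})"
        )
    if snr_plus == 0:
        return None
    return snr_minus / snr_plus


def call_candidates(
    inputs: Sequence[tuple[str, float, float] | CompetitionResult | Mapping],
    thresholds: CallThresholds = CallThresholds(),
    annotations: Mapping[str, str] | None = None,
    score_precision: int | None = None,
) -> tuple[CompetitionResult, ...]:
    """Apply the dual inclusive filter to per-protein SNR pairs.

    ``inputs`` supplies (protein_id, snr_minus, snr_plus) triples —
    plain tuples, mappings with those keys, or :class:`CompetitionResult`
    records to be re-thresholded.  Output is sorted by SNR(−) descending
    with ties broken by protein_id ascending.  An undefined score
    (SNR(+) = 0) passes the score cutoff but is flagged
    ``complete_suppression``.

    ``score_precision`` rounds the calling score half-up to that many
    decimals *for thresholding only*.  Scoring freshly quantified scans
    uses full precision (the default); thresholding a published table
    whose SNR columns are themselves printed roundings is done at the
    table's printed precision, so a score that prints as 2.60 passes an
    inclusive 2.6 cutoff.  The reported ``calling_score`` always keeps
    full precision.
    """
    triples: list[tuple[str, float, float]] = []
    for item in inputs:
        if isinstance(item, CompetitionResult):
            triples.append((item.protein_id, item.snr_minus, item.snr_plus))
        elif isinstance(item, Mapping):
            triples.append(
                (item["protein_id"], float(item["snr_minus"]), float(item["snr_plus"]))
            )
        else:
            pid, minus, plus = item
            triples.append((pid, float(minus), float(plus)))

    ids = [t[0] for t in triples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate protein_id in inputs: {dupes}")

    annotations = annotations or {}
    results = []
    for pid, minus, plus in triples:
        score = calling_score(minus, plus)
        flags: tuple[str, ...] = ()
        if score is None:
            score_passes = True
            flags = (COMPLETE_SUPPRESSION,)
        else:
            effective = (
                score
                if score_precision is None
                else round_half_up(score, score_precision)
            )
            score_passes = effective >= thresholds.calling_score_min
        results.append(
            CompetitionResult(
                protein_id=pid,
                snr_minus=minus,
                snr_plus=plus,
                calling_score=score,
                is_candidate=(minus >= thresholds.snr_minus_min) and score_passes,
                flags=flags,
                annotation=annotations.get(pid),
            )
        )
    results.sort(key=lambda r: (-r.snr_minus, r.protein_id))
    return tuple(results)


def score_pair(
    minus: ArrayScan,
    plus: ArrayScan,
    thresholds: CallThresholds = CallThresholds(),
    annotations: Mapping[str, str] | None = None,
) -> PairScores:
    """Score a competitor-absent / competitor-present scan pair.

    Computes per-protein SNR on each scan, inner-joins by protein
    identifier, and applies the dual filter.  Proteins present (usable)
    in only one scan go to ``unpaired``; proteins unusable in both go to
    ``excluded``.  No between-array normalization is applied.
    """
    if Condition(minus.condition) is not Condition.MINUS_COMPETITOR:
        raise ConditionError(
            f"scan {minus.scan_id!r} passed as minus-competitor has "
            f"condition {Condition(minus.condition).value}"
        )
    if Condition(plus.condition) is not Condition.PLUS_COMPETITOR:
        raise ConditionError(
            f"scan {plus.scan_id!r} passed as plus-competitor has "
            f"condition {Condition(plus.condition).value}"
        )

    table_minus = protein_snr(minus)
    table_plus = protein_snr(plus)
    snr_minus = table_minus.as_dict()
    snr_plus = table_plus.as_dict()

    shared = snr_minus.keys() & snr_plus.keys()
    all_ids = snr_minus.keys() | snr_plus.keys()
    unpaired = tuple(sorted(all_ids - shared))
    excluded = tuple(sorted(set(table_minus.excluded) & set(table_plus.excluded)))

    results = call_candidates(
        [(pid, snr_minus[pid].snr, snr_plus[pid].snr) for pid in sorted(shared)],
        thresholds,
        annotations=annotations,
    )
    return PairScores(results=results, unpaired=unpaired, excluded=excluded)
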