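"""Synthetic lectin-competition assay generator with known ground truth.

Emulates the screen's design at full scale — 4,256 arrayed proteins,
each spotted in duplicate, histone-like positive controls, and a paired
competitor-absent / competitor-present scan — so the caller's operating
characteristics (sensitivity, specificity, threshold behaviour) are
measurable without any external data.

Generative model
----------------
Each protein carries one latent class:

* ``glycoprotein`` — lectin binding is glycan-dependent: true SNR under
  competition is ``true_snr_minus / true_suppression`` with suppression
  ≥ 1 drawn uniformly over a range spanning the published candidates'
  observed fold-suppressions.
* ``nonspecific_binder`` — binds the lectin itself; signal persists
  under competition (suppression exactly 1).
* ``non_binder`` — true SNR 1 in both conditions (indistinguishable
  from background).

Per spot, the background median is ``background_mean`` times a
multiplicative log-normal noise factor with coefficient of variation
``spot_cv`` (mean exactly 1, so intensities stay unbiased), and the
foreground median is the background times the condition's true SNR
times an independent log-normal factor.  Replicate spots get
independent noise.  ``spot_cv = 0`` yields exact generative identities,
the basis of the noise-free oracle tests.

Determinism: all randomness flows through one ``numpy`` PCG64 generator
seeded from ``params.seed``.  The draw sequence is fixed — (1) a
permutation assigning classes, (2) uniform effect sizes for
glycoproteins then nonspecific binders, (3) uniform suppressions,
(4) per-scan background then foreground noise vectors (minus scan first)
— so one seed reproduces bit-identical scans, truth, and emitted files.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .microarray_io import (
    ArrayScan,
    Condition,
    SpotKind,
    SpotRecord,
    write_gpr,
)

__all__ = [
    "ProteinClass",
    "SimulationParams",
    "TruthRecord",
    "GroundTruth",
    "SimulatedPair",
    "simulate_pair",
    "emit_fixture",
]

#: Grid geometry of emitted scans (spots filled row-major per block).
_BLOCK_ROWS = 32
_BLOCK_COLS = 32

#: Positive-control features: (name, true SNR in both conditions).
#: Strong, competitor-insensitive, mimicking the printed histone controls.
_CONTROLS: tuple[tuple[str, float], ...] = (("Histone_H3", 80.0), ("Histone_H4", 80.0))

#: Number of empty buffer spots appended per scan (true SNR 1).
_N_BUFFER = 2


class ProteinClass(str, enum.Enum):
    GLYCOPROTEIN = "glycoprotein"
    NONSPECIFIC_BINDER = "nonspecific_binder"
    NON_BINDER = "non_binder"


@dataclass(frozen=True, slots=True)
class SimulationParams:
    """Generative settings for one simulated assay.

    Defaults mirror the published screen: 4,256 proteins in duplicate;
    ~0.5% glycoproteins (≈ 23/4256, the observed hit rate) with true
    SNR(−) spanning the candidates' observed 20.33–152.91 and
    fold-suppression spanning their 2.57–12.08; 1% nonspecific binders.
    ``spot_cv`` is the per-spot multiplicative log-normal coefficient of
    variation (unitless; 0 disables noise).
    """

    n_proteins: int = 4256
    n_replicates: int = 2
    frac_glyco: float = 0.005
    frac_nonspecific: float = 0.01
    glyco_snr_range: tuple[float, float] = (20.0, 160.0)
    suppression_range: tuple[float, float] = (2.5, 13.0)
    nonspecific_snr_range: tuple[float, float] = (5.0, 50.0)
    background_mean: float = 500.0
    spot_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ParameterError("n_proteins and n_replicates must be >= 1")
        if not (0 <= self.frac_glyco <= 1 and 0 <= self.frac_nonspecific <= 1):
            raise ParameterError("class fractions must lie in [0, 1]")
        if self.frac_glyco + self.frac_nonspecific > 1:
            raise ParameterError("frac_glyco + frac_nonspecific must be <= 1")
        for name in ("glyco_snr_range", "suppression_range", "nonspecific_snr_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ParameterError(f"{name} must satisfy 0 < low <= high")
        if self.suppression_range[0] < 1:
            raise ParameterError("suppression lower bound must be >= 1")
        if self.background_mean <= 0:
            raise ParameterError("background_mean must be positive")
        if self.spot_cv < 0:
            raise ParameterError("spot_cv must be non-negative")


@dataclass(frozen=True, slots=True)
class TruthRecord:
    protein_id: str
    protein_class: ProteinClass
    true_snr_minus: float
    true_suppression: float


@dataclass(frozen=True)
class GroundTruth:
    """Latent per-protein truth of one simulated assay."""

    records: Mapping[str, TruthRecord]

    def __getitem__(self, protein_id: str) -> TruthRecord:
        return self.records[protein_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.records

    def ids_of_class(self, cls: ProteinClass) -> frozenset[str]:
        return frozenset(
            pid for pid, r in self.records.items() if r.protein_class is cls
        )

    @property
    def glycoproteins(self) -> frozenset[str]:
        return self.ids_of_class(ProteinClass.GLYCOPROTEIN)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": list(self.records),
                "protein_class": [r.protein_class.value for r in self.records.values()],
                "true_snr_minus": [r.true_snr_minus for r in self.records.values()],
                "true_suppression": [
                    r.true_suppression for r in self.records.values()
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        records = {
            r["protein_id"]: TruthRecord(
                protein_id=r["protein_id"],
                protein_class=ProteinClass(r["protein_class"]),
                true_snr_minus=float(r["true_snr_minus"]),
                true_suppression=float(r["true_suppression"]),
            )
            for r in df.to_dict("records")
        }
        return cls(records=records)


@dataclass(frozen=True)
class SimulatedPair:
    minus: ArrayScan
    plus: ArrayScan
    truth: GroundTruth
    params: SimulationParams


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV.

    sigma² = ln(1 + cv²) and mu = −sigma²/2 give E[factor] = 1.  With
    cv = 0 the draw degenerates to exactly 1.0 while still consuming
    ``size`` generator draws, keeping the stream layout cv-independent.
    """
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mu = -0.5 * sigma * sigma
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def _grid_position(index: int) -> tuple[int, int, int]:
    per_block = _BLOCK_ROWS * _BLOCK_COLS
    block, within = divmod(index, per_block)
    row, col = divmod(within, _BLOCK_COLS)
    return block + 1, row + 1, col + 1


def _build_scan(
    scan_id: str,
    condition: Condition,
    spot_ids: list[str],
    spot_kinds: list[SpotKind],
    true_snr: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
    competitor_name: str | None,
) -> ArrayScan:
    n = len(spot_ids)
    bg = params.background_mean * _lognormal_factors(rng, params.spot_cv, n)
    fg = bg * true_snr * _lognormal_factors(rng, params.spot_cv, n)
    spots = []
    for i in range(n):
        block, row, col = _grid_position(i)
        spots.append(
            SpotRecord(
                block=block,
                row=row,
                column=col,
                protein_id=spot_ids[i],
                spot_kind=spot_kinds[i],
                fg_median=float(fg[i]),
                bg_median=float(bg[i]),
                flag=0,
            )
        )
    return ArrayScan(
        scan_id=scan_id,
        condition=condition,
        spots=spots,
        lectin_name="WGA",
        competitor_name=competitor_name,
    )


def simulate_pair(params: SimulationParams) -> SimulatedPair:
    """Generate a paired competitor-absent/-present assay with truth.

    Class counts are deterministic (``round(frac × n)``); which proteins
    get which class is decided by one seeded permutation.  See the
    module docstring for the full draw sequence.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    protein_ids = [f"ECK{i + 1:04d}" for i in range(n)]

    n_glyco = int(round(params.frac_glyco * n))
    n_nonspec = int(round(params.frac_nonspecific * n))
    if n_glyco + n_nonspec > n:  # rounding at tiny n
        n_nonspec = n - n_glyco
    order = rng.permutation(n)
    glyco_idx = order[:n_glyco]
    nonspec_idx = order[n_glyco : n_glyco + n_nonspec]

    snr_minus = np.ones(n)
    suppression = np.ones(n)
    snr_minus[glyco_idx] = rng.uniform(*params.glyco_snr_range, size=n_glyco)
    snr_minus[nonspec_idx] = rng.uniform(
        *params.nonspecific_snr_range, size=n_nonspec
    )
    suppression[glyco_idx] = rng.uniform(*params.suppression_range, size=n_glyco)

    classes: list[ProteinClass] = [ProteinClass.NON_BINDER] * n
    for i in glyco_idx:
        classes[i] = ProteinClass.GLYCOPROTEIN
    for i in nonspec_idx:
        classes[i] = ProteinClass.NONSPECIFIC_BINDER

    records = {
        protein_ids[i]: TruthRecord(
            protein_id=protein_ids[i],
            protein_class=classes[i],
            true_snr_minus=float(snr_minus[i]),
            true_suppression=float(suppression[i]),
        )
        for i in range(n)
    }
    truth = GroundTruth(records=records)

    # Spot layout: replicate spots adjacent, then controls, then buffers.
    spot_ids: list[str] = []
    spot_kinds: list[SpotKind] = []
    spot_truth_minus: list[float] = []
    spot_truth_plus: list[float] = []
    for i in range(n):
        for _ in range(params.n_replicates):
            spot_ids.append(protein_ids[i])
            spot_kinds.append(SpotKind.SAMPLE)
            spot_truth_minus.append(snr_minus[i])
            spot_truth_plus.append(snr_minus[i] / suppression[i])
    for name, control_snr in _CONTROLS:
        for _ in range(params.n_replicates):
            spot_ids.append(name)
            spot_kinds.append(SpotKind.POSITIVE_CONTROL)
            spot_truth_minus.append(control_snr)
            spot_truth_plus.append(control_snr)
    for _ in range(_N_BUFFER):
        spot_ids.append("")
        spot_kinds.append(SpotKind.BUFFER)
        spot_truth_minus.append(1.0)
        spot_truth_plus.append(1.0)

    minus = _build_scan(
        "sim_minus",
        Condition.MINUS_COMPETITOR,
        spot_ids,
        spot_kinds,
        np.asarray(spot_truth_minus),
        params,
        rng,
        competitor_name=None,
    )
    plus = _build_scan(
        "sim_plus",
        Condition.PLUS_COMPETITOR,
        spot_ids,
        spot_kinds,
        np.asarray(spot_truth_plus),
        params,
        rng,
        competitor_name="chitin hydrolysate",
    )
    return SimulatedPair(minus=minus, plus=plus, truth=truth, params=params)


def emit_fixture(pair: SimulatedPair, dir_path: str | Path) -> dict[str, Path]:
    """Write a simulated pair to disk: two GPR scans, truth TSV, params YAML.

    The four files are sufficient to re-run scoring from disk; emission
    is deterministic (same pair → byte-identical files).  Returns the
    paths keyed by role.
    """
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "minus": out / "minus_competitor.gpr",
        "plus": out / "plus_competitor.gpr",
        "truth": out / "truth.tsv",
        "params": out / "params.yaml",
    }
    write_gpr(pair.minus, paths["minus"])
    write_gpr(pair.plus, paths["plus"])
    pair.truth.write_tsv(paths["truth"])
    record = dataclasses.asdict(pair.params)
    record["glyco_snr_range"] = list(record["glyco_snr_range"])
    record["suppression_range"] = list(record["suppression_range"])
    record["nonspecific_snr_range"] = list(record["nonspecific_snr_range"])
    paths["params"].write_text(
        yaml.safe_dump(record, sort_keys=True), encoding="utf-8"
    )
    return paths
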