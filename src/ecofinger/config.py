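"""Configuration objects for the synthetic-cohort generators.

The defaults describe a multiregional liver-cancer style study: several
patients, each sampled in three tumor cores (T1-T3), one tumor border (B)
and one adjacent normal tissue (N); malignant cells carry patient-specific
expression programs and contiguous chromosomal gains, non-malignant cells
share cell-type programs across patients, and two tumor-macrophage
ligand-receptor pairs (LGALS9-SLC1A5 and SPP1-PTGER4) are planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml

#: non-malignant cell types emitted by the cohort generator
NONMALIGNANT_TYPES = (
    "T",
    "B-cell",
    "TAM",
    "CAF",
    "TEC",
    "hepatocyte",
    "cholangiocyte",
)

#: the four fingerprint genes validated in situ (tumor-TAM communication)
FINGERPRINT_GENES = ("LGALS9", "SLC1A5", "SPP1", "PTGER4")
FINGERPRINT_PAIRS = (("LGALS9", "SLC1A5"), ("SPP1", "PTGER4"))

#: CD3 complex genes used for the T-cell purity filter
CD3_GENES = ("CD3D", "CD3E", "CD3G")

TUMOR_REGIONS = ("T1", "T2", "T3", "B")
NORMAL_REGION = "N"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class GainRegion:
    """A contiguous chromosomal span with a multiplicative copy-gain.

    ``start``/``end`` are fractional positions along the chromosome in
    [0, 1]; ``fold_change`` multiplies the expected expression of every
    gene inside the span in malignant cells.
    """

    chromosome: str
    start: float
    end: float
    fold_change: float

    def __post_init__(self):
        if not (0.0 <= self.start < self.end <= 1.0):
            raise ConfigurationError(
                f"gain span must satisfy 0 <= start < end <= 1, got "
                f"({self.start}, {self.end})"
            )
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be positive")


@dataclass(frozen=True)
class PlantedPair:
    """A ligand-receptor pair planted into designated cell types.

    ``direction`` is ``"tumor_to_tme"`` (ligand elevated in malignant
    cells, receptor in ``partner_celltype``) or ``"tme_to_tumor"`` (the
    reverse).  ``patients`` gates the malignant-compartment gene
    (``None`` plants it in every patient); ``partner_patients`` gates
    the partner-compartment gene and defaults to ``patients`` — passing
    an explicit tuple decouples the two, e.g. patient-specific tumor
    ligands against a TME receptor program shared by all patients.
    """

    ligand: str
    receptor: str
    partner_celltype: str = "TAM"
    patients: Optional[tuple] = None
    effect: float = 2.0
    direction: str = "tumor_to_tme"
    partner_patients: Optional[tuple] = None

    def __post_init__(self):
        if self.direction not in ("tumor_to_tme", "tme_to_tumor"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.ligand == self.receptor:
            raise ConfigurationError("ligand and receptor must differ")
        if self.effect <= 0:
            raise ConfigurationError("effect must be positive")


def default_gains(n_chromosomes: int = 10) -> tuple:
    # distal halves of two chromosomes: with 10 equal chromosomes this is
    # 10% of the genome at 2x, echoing recurrent 1q/8q gains in liver cancer
    second = min(8, n_chromosomes)
    gains = [GainRegion("chr1", 0.5, 1.0, 2.0)]
    if second > 1:
        gains.append(GainRegion(f"chr{second}", 0.5, 1.0, 2.0))
    return tuple(gains)


def default_planted_pairs() -> tuple:
    return (
        PlantedPair("SPP1", "PTGER4", "TAM", None, 2.0, "tumor_to_tme"),
        PlantedPair("LGALS9", "SLC1A5", "TAM", None, 2.0, "tme_to_tumor"),
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, bulk and spatial generators.

    A fixed ``seed`` makes every generator byte-identical across runs.
    """

    seed: int = 0
    n_patients: int = 6
    regions_per_patient: Sequence[str] = ("T1", "T2", "T3", "B", "N")
    n_malignant_per_region: int = 60
    n_per_celltype: int = 30
    n_genes: int = 2000
    n_chromosomes: int = 10
    gain_regions: Optional[Sequence[GainRegion]] = None
    planted_pairs: Sequence[PlantedPair] = field(
        default_factory=default_planted_pairs
    )
    baseline_dispersion: float = 0.3

    # expression model
    base_mean_log_median: float = 0.1   # median counts/cell of a gene
    base_mean_log_sigma: float = 1.2
    pair_base_mean: float = 1.5         # baseline counts of planted-pair genes
    n_markers_per_type: int = 20
    marker_strength: float = 6.0
    n_program_genes: int = 150          # patient-specific malignant program
    program_sigma: float = 0.8
    library_size_sigma: float = 0.3
    border_shift_sigma: float = 0.0     # optional B-region program shift

    # bulk cohort / survival
    n_bulk_samples: int = 200
    survival_hazards: dict = field(
        default_factory=lambda: {"1": 0.08, "2": 0.08 / 3.0}
    )
    censoring_rate: float = 0.2
    bulk_effect: float = 2.0            # pair elevation in cluster-1 samples

    def __post_init__(self):
        self.regions_per_patient = tuple(self.regions_per_patient)
        if self.gain_regions is None:
            self.gain_regions = default_gains(self.n_chromosomes)
        self.gain_regions = tuple(
            g if isinstance(g, GainRegion) else GainRegion(**g)
            for g in self.gain_regions
        )
        self.planted_pairs = tuple(
            p if isinstance(p, PlantedPair) else PlantedPair(**p)
            for p in self.planted_pairs
        )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "n_patients",
            "n_genes",
            "n_chromosomes",
            "n_per_celltype",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_malignant_per_region < 0:
            raise ConfigurationError("n_malignant_per_region must be >= 0")
        if self.n_malignant_per_region == 0 and self.planted_pairs:
            raise ConfigurationError(
                "planted ligand-receptor pairs require malignant cells "
                "(n_malignant_per_region >= 1)"
            )
        if self.baseline_dispersion <= 0:
            raise ConfigurationError("baseline_dispersion must be positive")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        for cluster, hazard in self.survival_hazards.items():
            if hazard <= 0:
                raise ConfigurationError(
                    f"hazard for cluster {cluster!r} must be > 0"
                )
        chroms = set(self.chromosome_names())
        for gain in self.gain_regions:
            if gain.chromosome not in chroms:
                raise ConfigurationError(
                    f"gain names unknown chromosome {gain.chromosome!r}"
                )
        patients = set(self.patient_ids())
        for pair in self.planted_pairs:
            for subset in (pair.patients, pair.partner_patients):
                if subset is not None and not set(subset) <= patients:
                    raise ConfigurationError(
                        f"planted pair {pair.ligand}-{pair.receptor} names "
                        f"patients outside the cohort"
                    )
            if pair.partner_celltype not in NONMALIGNANT_TYPES:
                raise ConfigurationError(
                    f"unknown partner cell type {pair.partner_celltype!r}"
                )

    # -- helpers ---------------------------------------------------------
    def patient_ids(self) -> list:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    def chromosome_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)
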