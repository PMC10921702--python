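"""Simulation configuration and planted ground truth.

`SimConfig` collects every tunable of the synthetic-data generator: the
fractionation design (cell lines x organelle fractions x replicates), the
planted PM-resident proteins and their log2 enrichment, the abundance-
dependent (MNAR) missingness mechanism, the annotation panels, and the
survival cohort. `GroundTruth` records what was planted so recovery can be
scored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic organellar-proteomics study.

    Abundances are simulated on the log2 scale: protein baselines are drawn
    from N(baseline_mean, baseline_sd), a protein's home compartment adds
    ``delta_pm`` log2 units in the fraction(s) where that compartment is
    enriched, and replicate noise is N(0, sigma_noise). An entry is then
    masked missing with probability ``logistic(mnar_slope * (mnar_midpoint -
    abundance))``; ``mnar_slope == 0`` disables missingness entirely.
    """

    n_proteins: int = 5000
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3", "CL4")
    fractions: tuple[str, ...] = ("PM", "cytosol", "mitochondria", "microsome", "nuclear")
    pm_fraction: str = "PM"
    n_replicates: int = 3

    # planted plasma-membrane signal
    n_planted_pm: int = 50
    n_exclusive_markers: int = 1
    delta_pm: float = 3.0
    sigma_noise: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    # abundance-dependent missingness (MNAR)
    mnar_midpoint: float = 5.0
    mnar_slope: float = 1.0

    # annotation panels
    annotation_noise: float = 0.05   # fraction of non-PM proteins passing GS/SPC
    n_cancer_lines: int = 142
    cancer_rate_exclusive: float = 0.01
    cancer_rate_background: float = 0.30
    antibody_rate: float = 0.85

    # normal-tissue panels
    n_tissues: int = 30
    ihc_level_probs: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    panel_meanlog: float = 5.0
    panel_sdlog: float = 1.0
    rna_meanlog: float = 3.0
    rna_sdlog: float = 1.0

    # survival cohort
    n_patients: int = 25
    true_hr: float = 5.0
    censor_rate: float = 0.30
    eor_log_hr: float = -0.5
    rt_log_hr: float = -0.4
    baseline_hazard_pfi: float = 0.02
    baseline_hazard_os: float = 0.01

    # junk rows emitted into the protein-groups file to exercise ingestion filters
    n_decoy_rows: int = 20
    n_contaminant_rows: int = 10
    n_single_peptide_rows: int = 15

    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if self.pm_fraction not in self.fractions:
            raise ValueError(f"pm_fraction {self.pm_fraction!r} not in fractions")
        if sum(f == self.pm_fraction for f in self.fractions) != 1:
            raise ValueError("exactly one fraction must be the PM fraction")
        if len(set(self.fractions)) != len(self.fractions):
            raise ValueError("fraction labels must be unique")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("cell-line labels must be unique")
        if not 0 < self.n_planted_pm < self.n_proteins:
            raise ValueError("need 0 < n_planted_pm < n_proteins")
        if not 0 <= self.n_exclusive_markers <= self.n_planted_pm:
            raise ValueError("exclusive markers must be a subset of planted PM proteins")
        if self.delta_pm < 0:
            raise ValueError("delta_pm must be non-negative")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if self.mnar_slope < 0:
            raise ValueError("mnar_slope must be non-negative")
        if not 0 <= self.annotation_noise <= 1:
            raise ValueError("annotation_noise must be in [0, 1]")
        for name in ("cancer_rate_exclusive", "cancer_rate_background",
                     "antibody_rate", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_tissues <= 0 or self.n_cancer_lines <= 0:
            raise ValueError("panel sizes must be positive")
        if abs(sum(self.ihc_level_probs) - 1.0) > 1e-9:
            raise ValueError("ihc_level_probs must sum to 1")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted.

    ``compartment_of`` maps every protein to its home compartment
    (``PM`` / ``cytosolic`` / ``membrane`` / ``nuclear``); ``pm_protein_ids``
    are the planted PM residents, ``exclusive_marker_ids`` the tumour-
    exclusive surface candidates among them, and ``patient_risk_group`` the
    planted upper-tertile assignment of the survival cohort (filled in once
    the cohort has been generated).
    """

    pm_protein_ids: frozenset[str]
    compartment_of: Mapping[str, str]
    exclusive_marker_ids: frozenset[str]
    patient_risk_group: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exclusive_marker_ids <= self.pm_protein_ids:
            raise ValueError("exclusive markers must be planted PM proteins")
        missing = self.pm_protein_ids - set(self.compartment_of)
        if missing:
            raise ValueError(f"compartment_of missing {len(missing)} planted proteins")
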