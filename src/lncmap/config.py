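"""Configuration for the synthetic multi-omics cohort generator.

The defaults describe the reference synthetic study: a pan-cancer-like cohort
of 300 samples profiled for 3,000 mRNAs and 300 lncRNAs (plus promoter
methylation and gene-level copy number), 40 co-essential modules of which 20
are driven by planted regulator lncRNAs and 20 are decoys (syntenic,
low-density, or plain nulls), 10 negative-binomial treatment/control count
datasets, exponential survival with expression-linked hazard, and point-source
binding peaks near a subset of lncRNA transcription start sites.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Tuple

import yaml


@dataclass
class SynthConfig:
    """All knobs of the synthetic data generator.

    Effect sizes are on the z-score (standardized) scale; fractions are in
    [0, 1].  Identical config + seed yields byte-identical outputs.
    """

    # cohort dimensions
    n_samples: int = 300
    n_genes: int = 3000
    n_lncrnas: int = 300
    n_essential: int = 400

    # module structure
    n_modules: int = 40
    n_driver_modules: int = 20
    module_size_range: Tuple[int, int] = (10, 30)
    frac_syntenic_decoys: float = 0.35
    frac_lowdensity_decoys: float = 0.35
    density_range: Tuple[float, float] = (0.5, 0.95)

    # regression signal structure
    beta_lnc_effect: float = 0.5
    beta_dm_effect: float = 0.5
    beta_cnv_effect: float = 0.5
    noise_sd: float = 1.0
    cnv_lnc_coupling: float = 0.7
    frac_confounded: float = 0.1
    frac_low_expressed: float = 0.05
    n_driver_inducers: int = 10
    n_driver_suppressors: int = 10

    # treatment count datasets
    n_treatment_datasets: int = 10
    n_treatment_replicates: int = 4
    treatment_log2fc: float = 1.585  # 3-fold planted shift
    treatment_consistency: float = 0.8  # fraction of datasets carrying the shift
    n_dataset_specific: int = 20
    nb_dispersion: float = 0.1
    nb_mean_log: float = 5.3
    nb_mean_sd: float = 1.0

    # survival
    n_prognostic: int = 10
    hazard_log_hr: float = 0.7  # per SD of expression
    censor_rate: float = 0.3
    baseline_hazard: float = 0.1

    # binding peaks near TSS
    n_peak_datasets: int = 12
    n_peak_proximal: int = 10
    peak_window_frac: float = 0.8  # fraction of datasets with a proximal peak
    n_background_peaks: int = 200
    peak_halfwidth: int = 100
    tss_window: int = 10000

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
            "n_lncrnas": self.n_lncrnas,
            "n_essential": self.n_essential,
            "n_modules": self.n_modules,
            "n_driver_modules": self.n_driver_modules,
            "n_treatment_datasets": self.n_treatment_datasets,
            "n_treatment_replicates": self.n_treatment_replicates,
            "n_peak_datasets": self.n_peak_datasets,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_samples < 8:
            raise ValueError(
                "n_samples must be >= 8: the four-term regression needs "
                "residual degrees of freedom with margin"
            )
        fracs = {
            "frac_syntenic_decoys": self.frac_syntenic_decoys,
            "frac_lowdensity_decoys": self.frac_lowdensity_decoys,
            "frac_confounded": self.frac_confounded,
            "frac_low_expressed": self.frac_low_expressed,
            "treatment_consistency": self.treatment_consistency,
            "censor_rate": self.censor_rate,
            "peak_window_frac": self.peak_window_frac,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.density_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"density_range must be within [0, 1], got {self.density_range}")
        slo, shi = self.module_size_range
        if slo < 2 or slo > shi:
            raise ValueError(f"invalid module_size_range {self.module_size_range}")
        if shi > self.n_genes:
            raise ValueError(
                f"module_size_range upper bound {shi} exceeds n_genes {self.n_genes}"
            )
        if self.n_driver_modules > self.n_modules:
            raise ValueError("n_driver_modules cannot exceed n_modules")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("module_size_range", "density_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg
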