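"""Run configuration for panel design and targeted genotyping.

A :class:`RunConfig` bundles every numeric threshold used by the panel
designer and the genotyper.  Two presets mirror the published assay set-ups
for an autogamous large-cohort crop ("tomato-like") and a small-cohort crop
with an explicit MAF ascertainment rule ("eggplant-like"); "custom" starts
from the tomato-like values and expects the caller to override.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

MODES = ("tomato-like", "eggplant-like", "custom")


@dataclass
class RunConfig:
    """All tunable thresholds of the SPET design/genotyping pipeline.

    Coordinates handed to and returned by the public API are 1-based
    inclusive (VCF/GFF convention); BED output is 0-based half-open.
    """

    mode: str = "tomato-like"
    seed: int = 0

    # -- candidate SNP eligibility ------------------------------------
    #: minimum cohort alternative allele count; comparison is strict (>)
    #: when ``alt_count_strict`` else inclusive (>=).
    min_alt_count: int = 8
    alt_count_strict: bool = True
    #: minimum minor allele frequency (strict >); None disables the test.
    min_maf: float | None = None

    # -- spacing constraints (bp) -------------------------------------
    #: required distance when both SNPs of a pair lie in CDS.
    spacing_cds: int = 5_000
    #: required distance when either SNP of a pair is intron/UTR.
    spacing_intron_utr: int = 15_000

    # -- probe geometry ------------------------------------------------
    probe_length: int = 40
    #: target SNP must sit within this many bases past the probe 3' end.
    target_window: int = 25
    #: usable sequenced bases beyond the probe 3' end after trimming.
    readout_length: int = 110

    # -- pilot coverage selection --------------------------------------
    cov_mean_min: float = 46.0
    cov_mean_max: float = 90.0
    #: a pilot sample is "low" when depth <= threshold (inclusive) or
    #: < threshold (exclusive), per ``cov_low_inclusive``.
    cov_low_depth: int = 5
    cov_low_inclusive: bool = True
    #: probes with at least this many low samples are excluded.
    cov_max_low_samples: int = 4

    # -- genotype calling ----------------------------------------------
    #: minimum read depth to emit any call (hom or het).
    min_call_depth: int = 10
    #: minor-read fraction at or below which a genotype is homozygous.
    hom_max_minor_fraction: float = 0.04
    het_min_minor_fraction: float = 0.25
    het_max_minor_fraction: float = 0.50

    # -- site-level high-confidence filters ----------------------------
    min_mean_depth: float = 30.0
    #: minimum fraction of non-missing calls (vcftools --max-missing
    #: semantics: larger = stricter).
    max_missing: float = 0.80
    #: minimum fraction of samples callable for the re-call filter.
    genotyping_ratio: float = 0.80

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for name, lo, hi in (
            ("hom_max_minor_fraction", 0.0, 0.5),
            ("het_min_minor_fraction", 0.0, 0.5),
            ("het_max_minor_fraction", 0.0, 0.5),
            ("max_missing", 0.0, 1.0),
            ("genotyping_ratio", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.probe_length < 1 or self.target_window < 1 or self.readout_length < 1:
            raise ValueError("probe geometry values must be positive")
        if self.min_maf is not None and not 0.0 <= self.min_maf <= 0.5:
            raise ValueError(f"min_maf={self.min_maf} outside [0, 0.5]")

    @classmethod
    def for_mode(cls, mode: str, seed: int = 0, **overrides) -> "RunConfig":
        """Build a config preset for ``mode`` with optional overrides."""
        if mode in ("tomato-like", "custom"):
            base = dict(mode=mode, seed=seed)
        elif mode == "eggplant-like":
            base = dict(
                mode=mode,
                seed=seed,
                min_alt_count=4,
                alt_count_strict=False,
                min_maf=0.25,
                cov_mean_min=79.0,
                cov_mean_max=130.0,
                cov_low_depth=5,
                cov_low_inclusive=False,
                cov_max_low_samples=3,
                max_missing=0.95,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)

    def header_items(self) -> list[tuple[str, str]]:
        """(key, value) pairs recorded in output file headers."""
        items = [("spetkit_mode", self.mode), ("spetkit_seed", str(self.seed))]
        for f in dataclasses.fields(self):
            if f.name in ("mode", "seed"):
                continue
            items.append((f.name, str(getattr(self, f.name))))
        return items
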