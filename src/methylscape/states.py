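"""Cell-state parameterization and cohort design.

Six cell states are contrasted throughout the analysis: dermal fibroblasts
(deep PMDs over LADs), iPSCs (no PMDs, CAG-skewed mCH, reprogramming errors),
iPSC-derived RPE before and after xenotransplantation (iRPE/xRPE; shallow
PMDs, inherited errors; xRPE regains mCH), cultured primary RPE (cRPE; shallow
PMDs, no reprogramming errors) and native RPE (nRPE; no PMDs, high CAC-skewed
mCH). An ESC-like state is provided as the properly-reprogrammed reference
used when tracing DMR origins.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import CH_CONTEXTS, GenomeSpec

RPE_STATES = frozenset({"iRPE", "xRPE", "cRPE", "nRPE"})


class DesignError(ValueError):
    """Raised when a cohort design references unknown states or is malformed."""


def _zero_mch() -> dict:
    return {c: 0.0 for c in CH_CONTEXTS}


def _mch(base: float, **over) -> dict:
    d = {c: base for c in CH_CONTEXTS}
    d.update(over)
    return d


@dataclass
class CellStateParams:
    """Per-state simulation parameters; all rates are fractions in [0, 1]."""

    name: str
    baseline_mcg: float = 0.85
    pmd_depth: float = 0.0          # subtracted from baseline inside PMD LADs
    pmd_occupancy: float = 0.0      # fraction of LADs carrying a PMD
    mch_rates: dict = field(default_factory=_zero_mch)
    nonconversion: float = 0.005    # symmetric bisulfite error floor
    mean_depth: float = 10.0
    reprogrammed: bool = False      # inherits patient lineage errors
    flank_pmd: bool = False         # local PMDs around errored CGIs
    resolves_dmr_fate: bool = False  # xRPE: demethylates resolved-fate DMRs

    def __post_init__(self):
        rates = [self.baseline_mcg, self.pmd_depth, self.pmd_occupancy,
                 self.nonconversion, *self.mch_rates.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError(f"{self.name}: all rates must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError(f"{self.name}: mean_depth must be > 0")
        missing = set(CH_CONTEXTS) - set(self.mch_rates)
        if missing:
            raise ValueError(f"{self.name}: mch_rates missing {sorted(missing)}")


def default_states() -> dict:
    """The study's six cell states plus an ESC-like reference, with defaults."""
    ipsc_mch = _mch(0.006, CAG=0.050, CAC=0.020, CAA=0.015, CAT=0.015,
                    CTG=0.012, CCG=0.008)
    nrpe_mch = _mch(0.012, CAC=0.100, CAA=0.045, CAG=0.045, CAT=0.045, CTC=0.045)
    xrpe_mch = {c: 0.5 * v for c, v in nrpe_mch.items()}
    return {
        "Fibro": CellStateParams("Fibro", pmd_depth=0.35, pmd_occupancy=1.0),
        "iPSC": CellStateParams("iPSC", mch_rates=ipsc_mch, reprogrammed=True),
        "iRPE": CellStateParams("iRPE", pmd_depth=0.18, pmd_occupancy=0.70,
                                mch_rates=_mch(0.004), reprogrammed=True,
                                flank_pmd=True),
        "xRPE": CellStateParams("xRPE", pmd_depth=0.18, pmd_occupancy=0.70,
                                mch_rates=xrpe_mch, reprogrammed=True,
                                flank_pmd=True, resolves_dmr_fate=True),
        "cRPE": CellStateParams("cRPE", pmd_depth=0.15, pmd_occupancy=0.60),
        "nRPE": CellStateParams("nRPE", mch_rates=nrpe_mch),
        "ESC": CellStateParams("ESC", mch_rates=dict(ipsc_mch)),
    }


@dataclass(frozen=True)
class SampleSpec:
    name: str
    state: str
    patient: str        # donor/lineage identifier
    sex: str            # 'F' or 'M'
    environment: str    # 'in_vitro' or 'in_vivo'
    reprogrammed: bool


@dataclass
class CohortDesign:
    samples: list

    def __post_init__(self):
        if len({s.name for s in self.samples}) != len(self.samples):
            raise DesignError("duplicate sample names in design")
        for s in self.samples:
            if s.sex not in ("F", "M"):
                raise DesignError(f"{s.name}: sex must be 'F' or 'M'")

    def validate_states(self, states: dict) -> None:
        unknown = {s.state for s in self.samples} - set(states)
        if unknown:
            raise DesignError(f"design references unknown states: {sorted(unknown)}")

    @property
    def patients(self) -> list:
        seen = {}
        for s in self.samples:
            seen.setdefault(s.patient, s.sex)
        return list(seen)

    def by_state(self, state: str) -> list:
        return [s for s in self.samples if s.state == state]


def default_design() -> CohortDesign:
    """The 16-methylome cohort: two reprogramming lineages (patient 1 female,
    patient 2 male) plus four cRPE and four nRPE donors of mixed sex."""
    rows = []
    for i, sex in (("1", "F"), ("2", "M")):
        p = f"P{i}"
        rows += [SampleSpec(f"Fibro{i}", "Fibro", p, sex, "in_vitro", False),
                 SampleSpec(f"iPSC{i}", "iPSC", p, sex, "in_vitro", True),
                 SampleSpec(f"iRPE{i}", "iRPE", p, sex, "in_vitro", True),
                 SampleSpec(f"xRPE{i}", "xRPE", p, sex, "in_vivo", True)]
    for i, sex in (("1", "F"), ("2", "F"), ("3", "M"), ("4", "M")):
        rows.append(SampleSpec(f"cRPE{i}", "cRPE", f"C{i}", sex, "in_vitro", False))
    for i, sex in (("1", "F"), ("2", "F"), ("3", "M"), ("4", "M")):
        rows.append(SampleSpec(f"nRPE{i}", "nRPE", f"N{i}", sex, "in_vivo", False))
    return CohortDesign(rows)


@dataclass
class LineageErrors:
    """Reprogramming-induced errors shared by one patient's reprogrammed samples."""

    patient: str
    cgi_error_ids: list       # CGIs hypermethylated on reprogramming
    idmr_hyper_ids: list      # imprinted DMRs hypermethylated on reprogramming
    xci_escaped_genes: list   # XCI-subject genes demethylated (female lineages)


def plant_lineage_errors(genome: GenomeSpec, patient: str, sex: str, seed: int,
                         shared_fraction: float = 0.7,
                         n_extra_cgis: int = 7,
                         common_idmr_hyper: int = 6,
                         extra_idmr_hyper: int = 0,
                         escape_fraction: float = 0.10) -> LineageErrors:
    """Draw one patient's reprogramming-error sets.

    Most CGI errors (``shared_fraction`` of the error-prone pool) are common to
    every lineage, mimicking recurrently error-prone loci; the remainder are
    patient specific. A fixed core of iDMRs is hypermethylated in every
    lineage, with optional patient-specific extras.
    """
    common_rng = np.random.default_rng([seed, 9001])
    pool = list(genome.error_prone_cgis)
    n_shared = int(round(shared_fraction * len(pool)))
    shared = sorted(common_rng.choice(pool, size=n_shared, replace=False).tolist())
    core_idmr = sorted(common_rng.choice(genome.idmrs["name"].tolist(),
                                         size=min(common_idmr_hyper, len(genome.idmrs)),
                                         replace=False).tolist())

    prng = np.random.default_rng([seed, zlib.crc32(patient.encode())])
    eligible = genome.neutral_cgis or \
        genome.cgis.loc[genome.cgis["chrom"] != "chrX", "name"].tolist()
    other_cgis = sorted(set(eligible) - set(pool))
    extras = sorted(prng.choice(other_cgis, size=min(n_extra_cgis, len(other_cgis)),
                                replace=False).tolist())
    idmr_rest = sorted(set(genome.idmrs["name"]) - set(core_idmr))
    extra_idmrs = sorted(prng.choice(idmr_rest,
                                     size=min(extra_idmr_hyper, len(idmr_rest)),
                                     replace=False).tolist())
    escaped = []
    if sex == "F" and genome.xci_subject_genes:
        n_esc = int(round(escape_fraction * len(genome.xci_subject_genes)))
        escaped = sorted(prng.choice(genome.xci_subject_genes, size=n_esc,
                                     replace=False).tolist())
    return LineageErrors(patient=patient,
                         cgi_error_ids=sorted(shared + extras),
                         idmr_hyper_ids=sorted(core_idmr + extra_idmrs),
                         xci_escaped_genes=escaped)


def with_depth(states: dict, mean_depth: float) -> dict:
    """Convenience: the same states at a different sequencing depth."""
    return {k: replace(v, mean_depth=mean_depth) for k, v in states.items()}
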