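"""WGBS cohort simulation.

Per-site truth is assembled from the genome annotation and the cell-state
parameters (baseline mCG, LAD-coincident PMD depressions, CGI/promoter
hypomethylation, state-specific promoter programs, reprogramming errors with
lineage memory, imprinted-DMR and XCI structure, planted DMR etiologies,
per-context mCH rates). Observed counts are then drawn per emitted site:
total ~ Poisson(mean depth), methylated ~ Binomial(total, p'), where
p' = p(1-e) + (1-p)e folds in a symmetric bisulfite non-conversion error e.
CG sites are emitted on both strands; CH sites are strand-specific and carry
their trinucleotide context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .genome import GenomeSpec
from .states import (RPE_STATES, CellStateParams, CohortDesign, LineageErrors,
                     plant_lineage_errors)

HI, LO, MID = 0.85, 0.10, 0.45
CGI_LEVEL = 0.05
PROMOTER_LEVEL = 0.08
PROGRAM_LEVEL = 0.75
CGI_ERROR_LEVEL = 0.88
FLANK_PMD_DROP = 0.35
FLANK_PMD_SPAN = 5_000
XCI_MALE_LEVEL = 0.04
XCI_NONSUBJECT_LEVEL = 0.06
XCI_ESCAPED_LEVEL = 0.02

# planted DMR truth: per-etiology methylation level by cell state
_ETIOLOGY_LEVELS = {
    "demethylation-error": {"Fibro": HI, "iPSC": HI, "ESC": HI, "iRPE": HI,
                            "xRPE": HI, "cRPE": LO, "nRPE": LO},
    "maintenance-error": {"Fibro": HI, "iPSC": HI, "ESC": HI, "iRPE": LO,
                          "xRPE": LO, "cRPE": HI, "nRPE": HI},
    "de-novo-error": {"Fibro": LO, "iPSC": LO, "ESC": LO, "iRPE": LO,
                      "xRPE": LO, "cRPE": LO, "nRPE": MID},
    "reprogramming-error": {"Fibro": LO, "iPSC": HI, "ESC": LO, "iRPE": HI,
                            "xRPE": HI, "cRPE": LO, "nRPE": LO},
}


def planted_dmr_level(etiology: str, state: str, fate: str) -> float | None:
    """True methylation of a planted DMR in a given state (None = background)."""
    levels = _ETIOLOGY_LEVELS.get(etiology)
    if levels is None or state not in levels:
        return None
    if state == "xRPE" and fate == "resolved-in-xRPE":
        return _ETIOLOGY_LEVELS[etiology]["nRPE"]
    return levels[state]


def select_pmd_lads(genome: GenomeSpec, state: CellStateParams,
                    seed: int) -> pd.DataFrame:
    """Pick the LAD subset that carries PMDs in this sample (occupancy fraction)."""
    lads = genome.lads
    if state.pmd_occupancy <= 0 or len(lads) == 0:
        return lads.iloc[0:0][iv.BED_COLUMNS]
    rng = np.random.default_rng([seed, 777])
    n = int(round(state.pmd_occupancy * len(lads)))
    idx = np.sort(rng.choice(len(lads), size=n, replace=False))
    return lads.iloc[idx][iv.BED_COLUMNS].reset_index(drop=True)


def _set_by_intervals(p, pos, table, chrom, value):
    mask = iv.sites_in_intervals(pos, table, chrom)
    p[mask] = value
    return mask


def _promoter_intervals(genes: pd.DataFrame, chrom: str, names=None,
                        flank: int = 500) -> pd.DataFrame:
    g = genes[genes["chrom"] == chrom]
    if names is not None:
        g = g[g["name"].isin(set(names))]
    if len(g) == 0:
        return pd.DataFrame(columns=iv.BED_COLUMNS)
    return pd.DataFrame({"chrom": chrom,
                         "start": (g["tss"] - flank).clip(lower=0),
                         "end": g["tss"] + flank + 1})


def true_cg_levels(genome: GenomeSpec, state: CellStateParams, chrom: str,
                   sex: str = "F", lineage: LineageErrors | None = None,
                   pmd_intervals: pd.DataFrame | None = None,
                   region_levels: pd.DataFrame | None = None) -> np.ndarray:
    """Planted per-CpG methylation probability for one chromosome.

    ``region_levels`` (chrom, start, end, level) force arbitrary regions to a
    fixed level after all annotation-driven assignments; they are the hook for
    planting custom effects (e.g. calibrated group differences) in experiments
    that do not use the named cell states.
    """
    pos = genome.cpg_pos[chrom]
    p = np.full(len(pos), state.baseline_mcg)

    if pmd_intervals is not None and len(pmd_intervals):
        mask = iv.sites_in_intervals(pos, pmd_intervals, chrom)
        p[mask] -= state.pmd_depth

    for r in genome.planted_dmrs[genome.planted_dmrs["chrom"] == chrom].itertuples():
        lvl = planted_dmr_level(r.etiology, state.name, r.fate)
        if lvl is None:
            continue
        sel = (pos - 1 >= r.start) & (pos - 1 < r.end)
        p[sel] = lvl

    _set_by_intervals(p, pos, genome.idmrs, chrom, 0.5)
    if state.reprogrammed and lineage is not None and lineage.idmr_hyper_ids:
        hyper = genome.idmrs[genome.idmrs["name"].isin(lineage.idmr_hyper_ids)]
        _set_by_intervals(p, pos, hyper, chrom, 0.9)

    _set_by_intervals(p, pos, genome.cgis, chrom, CGI_LEVEL)
    _set_by_intervals(p, pos, _promoter_intervals(genome.genes, chrom),
                      chrom, PROMOTER_LEVEL)
    program = genome.state_programs.get(state.name, [])
    if program:
        _set_by_intervals(p, pos, _promoter_intervals(genome.genes, chrom, program),
                          chrom, PROGRAM_LEVEL)
    sig_level = CGI_LEVEL if state.name in RPE_STATES else PROGRAM_LEVEL
    _set_by_intervals(p, pos, _promoter_intervals(genome.genes, chrom,
                                                  genome.rpe_signature_genes),
                      chrom, sig_level)

    if state.reprogrammed and lineage is not None and lineage.cgi_error_ids:
        err = genome.cgis[genome.cgis["name"].isin(lineage.cgi_error_ids)]
        _set_by_intervals(p, pos, err, chrom, CGI_ERROR_LEVEL)
        if state.flank_pmd and len(err):
            flanks = pd.concat([
                pd.DataFrame({"chrom": err["chrom"],
                              "start": (err["start"] - FLANK_PMD_SPAN).clip(lower=0),
                              "end": err["start"]}),
                pd.DataFrame({"chrom": err["chrom"], "start": err["end"],
                              "end": err["end"] + FLANK_PMD_SPAN})])
            mask = iv.sites_in_intervals(pos, flanks, chrom)
            p[mask] = np.minimum(p[mask], state.baseline_mcg - FLANK_PMD_DROP)

    if chrom == "chrX":
        xg = genome.genes[genome.genes["chrom"] == "chrX"]
        subject = set(genome.xci_subject_genes)
        escaped = set(lineage.xci_escaped_genes) \
            if (state.reprogrammed and lineage is not None) else set()
        for r in xg.itertuples():
            sel = (pos - 1 >= r.tss - 500) & (pos - 1 < r.tss + 501)
            if sex == "M":
                p[sel] = XCI_MALE_LEVEL
            elif r.name not in subject:
                p[sel] = XCI_NONSUBJECT_LEVEL
            elif r.name in escaped:
                p[sel] = XCI_ESCAPED_LEVEL
            else:
                p[sel] = r.xci_female_level

    if region_levels is not None:
        for r in region_levels[region_levels["chrom"] == chrom].itertuples():
            sel = (pos - 1 >= r.start) & (pos - 1 < r.end)
            p[sel] = r.level

    return np.clip(p, 0.02, 0.98)


def simulate_methylome(genome: GenomeSpec, state: CellStateParams, seed: int, *,
                       sex: str = "F", lineage: LineageErrors | None = None,
                       pmd_intervals: pd.DataFrame | None = None,
                       region_levels: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate one sample's per-cytosine table (CG both strands + CH sites)."""
    rng = np.random.default_rng(seed)
    if pmd_intervals is None:
        pmd_intervals = select_pmd_lads(genome, state, seed)
    e = state.nonconversion
    frames = []
    for chrom in genome.chrom_lengths:
        p = true_cg_levels(genome, state, chrom, sex=sex, lineage=lineage,
                           pmd_intervals=pmd_intervals,
                           region_levels=region_levels)
        cpos = genome.cpg_pos[chrom]
        n = len(cpos)
        pos2 = np.repeat(cpos, 2)
        pos2[1::2] += 1
        strand2 = np.tile(np.array(["+", "-"]), n)
        p2 = np.repeat(p, 2)
        p_obs = p2 * (1 - e) + (1 - p2) * e
        total = rng.poisson(state.mean_depth, size=2 * n)
        meth = rng.binomial(total, p_obs)
        cg = pd.DataFrame({"chrom": chrom, "pos": pos2, "strand": strand2,
                           "context": "CG", "meth": meth, "total": total})

        ch = genome.ch_sites[chrom]
        rate = np.array([state.mch_rates[c] for c in ch["context"]])
        mult = np.ones(len(ch))
        hpos = ch["pos"].to_numpy(np.int64)
        for r in genome.genes[genome.genes["chrom"] == chrom].itertuples():
            lo = min(r.start, r.tss - 500)
            hi = max(r.end, r.tss + 501)
            sel = (hpos - 1 >= lo) & (hpos - 1 < hi)
            mult[sel] = r.mch_propensity
        p_ch = np.clip(rate * mult, 0.0, 0.95)
        p_ch = p_ch * (1 - e) + (1 - p_ch) * e
        tot_ch = rng.poisson(state.mean_depth, size=len(ch))
        meth_ch = rng.binomial(tot_ch, p_ch)
        chdf = pd.DataFrame({"chrom": chrom, "pos": hpos,
                             "strand": ch["strand"].to_numpy(),
                             "context": ch["context"].to_numpy(),
                             "meth": meth_ch, "total": tot_ch})
        both = pd.concat([cg, chdf], ignore_index=True)
        both = both.sort_values("pos", kind="mergesort").reset_index(drop=True)
        frames.append(both)
    out = pd.concat(frames, ignore_index=True)
    out["meth"] = out["meth"].astype(np.int32)
    out["total"] = out["total"].astype(np.int32)
    return out


def cohort_lineages(genome: GenomeSpec, design: CohortDesign, seed: int,
                    extra_idmr_hyper: dict | None = None) -> dict:
    """Per-patient reprogramming-error sets, shared by a lineage's samples.

    By default the second reprogramming lineage carries 13 extra
    hypermethylated iDMRs on top of the 6 common to every lineage, matching
    the asymmetry between the two patients the cohort emulates.
    """
    reprog_patients, sexes = [], {}
    for s in design.samples:
        sexes.setdefault(s.patient, s.sex)
        if s.reprogrammed and s.patient not in reprog_patients:
            reprog_patients.append(s.patient)
    if extra_idmr_hyper is None:
        extra_idmr_hyper = {p: (13 if i == 1 else 0)
                            for i, p in enumerate(reprog_patients)}
    return {p: plant_lineage_errors(genome, p, sexes[p], seed,
                                    extra_idmr_hyper=extra_idmr_hyper.get(p, 0))
            for p in reprog_patients}


def simulate_cohort(genome: GenomeSpec, design: CohortDesign, seed: int,
                    states: dict | None = None) -> tuple[dict, dict]:
    """Simulate every sample in the design; returns (tables, manifest).

    Reprogrammed samples of one patient share the same planted CGI, iDMR and
    XCI error sets (lineage memory). The manifest records all planted truth.
    """
    from .states import default_states
    states = states or default_states()
    design.validate_states(states)
    if len({s.state for s in design.samples}) < 1 or len(design.samples) < 1:
        raise ValueError("design must name at least one sample")
    lineages = cohort_lineages(genome, design, seed)
    tables, manifest_samples, pmd_truth = {}, [], {}
    for idx, spec in enumerate(design.samples):
        st = states[spec.state]
        sseed = np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31)
        pmds = select_pmd_lads(genome, st, int(sseed))
        lineage = lineages.get(spec.patient) if spec.reprogrammed else None
        tables[spec.name] = simulate_methylome(
            genome, st, int(sseed), sex=spec.sex, lineage=lineage,
            pmd_intervals=pmds)
        pmd_truth[spec.name] = pmds[iv.BED_COLUMNS].values.tolist()
        manifest_samples.append({"name": spec.name, "state": spec.state,
                                 "patient": spec.patient, "sex": spec.sex,
                                 "environment": spec.environment,
                                 "reprogrammed": spec.reprogrammed,
                                 "seed": int(sseed)})
    manifest = {
        "seed": seed,
        "samples": manifest_samples,
        "lineage_errors": {p: {"cgi_error_ids": l.cgi_error_ids,
                               "idmr_hyper_ids": l.idmr_hyper_ids,
                               "xci_escaped_genes": l.xci_escaped_genes}
                           for p, l in lineages.items()},
        "pmd_truth": pmd_truth,
        "planted_dmrs": genome.planted_dmrs.to_dict("records"),
    }
    return tables, manifest


@dataclass
class ExpressionCoupling:
    """Signed log2 effect sizes linking planted methylation to expression."""

    promoter_silencing_log2: float = -2.0   # methylated promoter -> repressed
    escape_log2: float = 1.0                # XCI escape -> ~2-fold derepression
    mch_slope_log2: float = -1.0            # per unit excess mCH propensity
    noise_sd: float = 0.15

    @classmethod
    def zero(cls):
        return cls(0.0, 0.0, 0.0, noise_sd=0.15)


def _cgi_to_gene(genome: GenomeSpec) -> dict:
    out = {}
    for r in genome.genes[genome.genes["has_cgi_promoter"]].itertuples():
        hits = genome.cgis[(genome.cgis["chrom"] == r.chrom)
                           & (genome.cgis["start"] <= r.tss)
                           & (genome.cgis["end"] > r.tss)]
        if len(hits):
            out[hits.iloc[0]["name"]] = r.name
    return out


def simulate_expression(genome: GenomeSpec, design: CohortDesign, seed: int,
                        coupling: ExpressionCoupling | None = None,
                        states: dict | None = None,
                        lineages: dict | None = None) -> pd.DataFrame:
    """Gene x sample FPKM table coupled to the planted methylation structure."""
    from .states import default_states
    coupling = coupling or ExpressionCoupling()
    states = states or default_states()
    if lineages is None:
        lineages = cohort_lineages(genome, design, seed)
    rng = np.random.default_rng([seed, 424242])
    genes = genome.genes
    base = rng.normal(3.0, 1.5, size=len(genes))
    cgi2gene = _cgi_to_gene(genome)
    nrpe_mean = np.mean(list(states["nRPE"].mch_rates.values())) if "nRPE" in states \
        else 0.035
    cols = {}
    for spec in design.samples:
        st = states[spec.state]
        lineage = lineages.get(spec.patient) if spec.reprogrammed else None
        silenced = set(genome.state_programs.get(spec.state, []))
        if spec.state not in RPE_STATES:
            silenced |= set(genome.rpe_signature_genes)
        if lineage is not None:
            silenced |= {cgi2gene[c] for c in lineage.cgi_error_ids if c in cgi2gene}
        escaped = set(lineage.xci_escaped_genes) \
            if (lineage is not None and spec.sex == "F") else set()
        s = (np.mean(list(st.mch_rates.values())) / nrpe_mean) if nrpe_mean else 0.0
        log2 = base.copy()
        log2 += np.where(genes["name"].isin(silenced),
                         coupling.promoter_silencing_log2, 0.0)
        log2 += np.where(genes["name"].isin(escaped), coupling.escape_log2, 0.0)
        log2 += coupling.mch_slope_log2 * s * (genes["mch_propensity"].to_numpy() - 1.0)
        log2 += rng.normal(0.0, coupling.noise_sd, size=len(genes))
        cols[spec.name] = np.power(2.0, log2)
    fpkm = pd.DataFrame(cols, index=genes["name"].to_numpy())
    fpkm.index.name = "gene"
    return fpkm
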