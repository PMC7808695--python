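"""End-to-end pipeline driver.

Runs the stages in study order — read QC and damage authentication,
screening, genetic sex and contamination, uniparental haplogroups,
pseudohaploid genotyping, IBS/MDS clustering, unsupervised admixture, and
radiocarbon calibration with diet-based reservoir correction — and collects
per-sample report tables. Stages after screening run only for samples that
pass screening, mirroring how deeper sequencing is restricted to the
best-preserved libraries.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import chrono, haplo, popgen, qc, sexcontam
from . import io as akio

log = logging.getLogger("ancientkin")

DEFAULT_THRESHOLDS = {
    "min_mapq": 30, "min_len": 30, "geno_min_bq": 30, "xcontam_min_bq": 20,
    "mt_min_depth": 3, "mt_end_trim": 7, "screen_endo": 0.5, "screen_ct5": 10.0,
    "x_doc_min": 0.5, "mt_doc_min": 5.0, "min_overlap": 500,
}

_PATH_KEYS = {"fasta", "vcf", "labels", "mt_defs_newick", "mt_defs_variants",
              "y_defs_newick", "y_defs_variants", "curve", "dates",
              "mt_contaminants"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``from_yaml``).

    ``sam`` maps sample id to SAM path; ``raw_reads`` maps sample id to the
    total raw (pre-alignment) read count used for the endogenous-content
    denominator; ``dates`` points to a TSV with columns sample_id, lab_id,
    uncal_bp, sigma and optionally delta13c for reservoir correction.
    """

    sam: dict
    raw_reads: dict
    paths: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    kmin: int = 2
    kmax: int = 6
    replicates: int = 10
    mt_contig: str = "chrMT"
    x_contig: str = "chrX"
    y_contig: str = "chrY"

    def __post_init__(self):
        merged = dict(DEFAULT_THRESHOLDS)
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        merged.update(self.thresholds)
        self.thresholds = merged
        unknown = set(self.paths) - _PATH_KEYS
        if unknown:
            raise ValueError(f"unknown path keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(cfg: PipelineConfig, outdir: Optional[Path] = None) -> dict:
    """Run every stage; return a report bundle of DataFrames plus statuses.

    Any stage failure is recorded in ``report['status']`` and later stages
    that depend on it are skipped; the partial report is still returned (and
    written when ``outdir`` is given).
    """
    report: dict = {"status": {}, "seed": cfg.seed}
    th = cfg.thresholds
    meta = {"config_hash": akio.config_hash(cfg.as_dict()), "seed": cfg.seed}
    reference = akio.read_fasta(cfg.paths["fasta"])
    comp_lengths = {c: len(s) for c, s in reference.items()}

    qc_rows, damage_profiles, screened, filtered_sets = [], {}, {}, {}
    for sample, sam_path in sorted(cfg.sam.items()):
        try:
            rs = akio.read_sam(sam_path, reference, sample_id=sample)
            flt = qc.filter_reads(rs, th["min_mapq"], th["min_len"])
            flt, n_dup = qc.collapse_duplicates(flt)
            dp = qc.damage_profile(flt)
            sq = qc.sample_qc(cfg.raw_reads[sample], flt, comp_lengths,
                              mt_contig=cfg.mt_contig, n_duplicates_removed=n_dup)
            decision, reasons = qc.screen_sample(sq, dp, th["screen_endo"],
                                                 th["screen_ct5"])
            filtered_sets[sample] = flt
            damage_profiles[sample] = dp
            screened[sample] = decision
            qc_rows.append({
                "sample": sample, "Endo%": round(sq.endogenous_pct, 2),
                "DoC": round(sq.doc_nuclear, 4), "MT DoC": round(sq.doc_mt, 2),
                "5' C-T %": (round(100 * dp.ct5[0], 1)
                             if not np.isnan(dp.ct5[0]) else None),
                "mean_fragment_bp": round(sq.mean_fragment_bp, 1),
                "n_raw": sq.n_reads_raw, "n_postfilter": sq.n_reads_postfilter,
                "n_duplicates_removed": sq.n_duplicates_removed,
                "screen": decision, "screen_reasons": "; ".join(reasons),
            })
            report["status"][f"qc:{sample}"] = "ok"
        except Exception as e:  # stage failure -> partial report
            report["status"][f"qc:{sample}"] = f"error: {e}"
            screened[sample] = "fail"
    report["qc"] = pd.DataFrame(qc_rows)
    passing = sorted(s for s, d in screened.items() if d == "pass")
    report["passing_samples"] = passing

    # --- sex, contamination, haplogroups ---------------------------------
    mt_defs = y_defs = None
    if "mt_defs_newick" in cfg.paths:
        mt_defs = akio.read_haplo_defs(cfg.paths["mt_defs_newick"],
                                       cfg.paths["mt_defs_variants"])
    if "y_defs_newick" in cfg.paths:
        y_defs = akio.read_haplo_defs(cfg.paths["y_defs_newick"],
                                      cfg.paths["y_defs_variants"])
    contaminants = None
    if "mt_contaminants" in cfg.paths:
        contaminants = list(akio.read_fasta(cfg.paths["mt_contaminants"]).values())

    sex_rows, haplo_rows = [], []
    for sample in passing:
        rs = filtered_sets[sample]
        try:
            nX, nY = sexcontam.count_sex_reads(rs, cfg.x_contig, cfg.y_contig)
            call = sexcontam.ry_sex(nX, nY)
            row = {"sample": sample, "nX": nX, "nY": nY,
                   "Ry": round(call.ry, 4),
                   "Ry CI": f"({call.ci_low:.4f}–{call.ci_high:.4f})",
                   "sex": call.assignment, "MT contam %": None,
                   "MT contam CI": None, "X contam %": None}
            doc_mt = (sum(len(r.seq) for r in rs.reads if r.contig == cfg.mt_contig)
                      / comp_lengths[cfg.mt_contig])
            consensus = sexcontam.mt_consensus(rs, cfg.mt_contig,
                                               th["mt_min_depth"], th["mt_end_trim"])
            if contaminants and doc_mt > th["mt_doc_min"]:
                est = sexcontam.mt_contamination(
                    rs, consensus, contaminants, contig=cfg.mt_contig,
                    end_trim=th["mt_end_trim"])
                row["MT contam %"] = round(100 * est.estimate, 2)
                row["MT contam CI"] = f"({100 * est.ci_low:.2f}–{100 * est.ci_high:.2f})"
            doc_x = (sum(len(r.seq) for r in rs.reads if r.contig == cfg.x_contig)
                     / comp_lengths[cfg.x_contig])
            if (call.assignment == "XY" and doc_x > th["x_doc_min"]
                    and "vcf" in cfg.paths):
                panel = _load_panel(cfg)
                if panel.x_sites is not None:
                    est = sexcontam.x_contamination(
                        rs, panel.x_sites, th["min_mapq"], th["xcontam_min_bq"],
                        x_contig=cfg.x_contig, seed=cfg.seed)
                    row["X contam %"] = round(100 * est.estimate, 2)
            sex_rows.append(row)
            report["status"][f"sexcontam:{sample}"] = "ok"
        except Exception as e:
            report["status"][f"sexcontam:{sample}"] = f"error: {e}"
            continue
        try:
            hrow = {"sample": sample, "mtDNA": None, "mt_score": None,
                    "Y": None, "Y_support": None}
            if mt_defs is not None:
                obs, cov = haplo.consensus_derived_variants(consensus, mt_defs)
                ranked = haplo.assign_mt_haplogroup(obs, mt_defs,
                                                    covered_positions=cov)
                hrow["mtDNA"] = ranked[0].haplogroup
                hrow["mt_score"] = (round(ranked[0].score, 3)
                                    if ranked[0].score is not None else None)
            if y_defs is not None and call.assignment == "XY":
                statuses = haplo.snp_status(rs.on_contig(cfg.y_contig),
                                            y_defs.all_variants(),
                                            min_bq=th["geno_min_bq"])
                place = haplo.place_on_tree(statuses, y_defs)
                hrow["Y"] = place.haplogroup
                hrow["Y_support"] = place.n_derived_support
            haplo_rows.append(hrow)
            report["status"][f"haplo:{sample}"] = "ok"
        except Exception as e:
            report["status"][f"haplo:{sample}"] = f"error: {e}"
    report["sexcontam"] = pd.DataFrame(sex_rows)
    report["haplogroups"] = pd.DataFrame(haplo_rows)

    # --- population genomics ---------------------------------------------
    if "vcf" in cfg.paths and passing:
        try:
            panel = _load_panel(cfg)
            M = panel.n_sites
            calls, cov_rows = {}, []
            for sample in passing:
                g = popgen.pseudohaploid_call(
                    filtered_sets[sample], panel, th["min_mapq"],
                    th["geno_min_bq"], seed=cfg.seed)
                calls[sample] = g
                n, pct = popgen.coverage_report(g, M)
                cov_rows.append({"sample": sample, "n_covered": n,
                                 "panel_size": M, "percent": pct})
            report["coverage"] = pd.DataFrame(cov_rows)
            hap_panel = popgen.haploidize(panel.genotypes, seed=cfg.seed)
            names = list(panel.individuals) + passing
            X = np.vstack([hap_panel] + [calls[s].calls[None, :] for s in passing])
            ibs = popgen.ibs_matrix(X, names, min_overlap=th["min_overlap"])
            report["ibs_individuals"] = names
            report["ibs_distance"] = ibs.distance
            keep = ~(ibs.flagged.any(axis=1) | np.isnan(ibs.distance).any(axis=1))
            if keep.sum() < 3:
                raise ValueError(
                    f"only {int(keep.sum())} individuals exceed the "
                    f"{th['min_overlap']}-site pairwise overlap floor")
            sub = ibs.distance[np.ix_(keep, keep)]
            coords, evals = popgen.classical_mds(sub)
            mds = pd.DataFrame({"individual": [n for n, k in zip(names, keep) if k],
                                "dim1": coords[:, 0], "dim2": coords[:, 1]})
            mds["population"] = [panel.labels.get(i, "ancient")
                                 for i in mds["individual"]]
            report["mds"] = mds
            report["status"]["popgen"] = "ok"
        except Exception as e:
            report["status"]["popgen"] = f"error: {e}"
        try:
            Gdip = panel.genotypes.astype(float)
            Ganc = np.vstack([calls[s].calls for s in passing]).astype(float)
            G = np.vstack([Gdip, Ganc])
            ploidy = np.array([2.0] * Gdip.shape[0] + [1.0] * Ganc.shape[0])
            admix_rows = []
            for K in range(cfg.kmin, cfg.kmax + 1):
                fits = [popgen.admixture_fit(G, ploidy, K,
                                             seed=cfg.seed * 1000 + K * 100 + r)
                        for r in range(cfg.replicates)]
                best, perms, members = popgen.align_modes(fits)
                for i, name in enumerate(names):
                    row = {"K": K, "individual": name,
                           "mode_size": len(members)}
                    for k in range(K):
                        row[f"Q{k + 1}"] = round(float(best.Q[i, k]), 4)
                    admix_rows.append(row)
            report["admixture"] = pd.DataFrame(admix_rows)
            report["status"]["admixture"] = "ok"
        except Exception as e:
            report["status"]["admixture"] = f"error: {e}"

    # --- chronology -------------------------------------------------------
    if "dates" in cfg.paths and "curve" in cfg.paths:
        try:
            curve = chrono.read_calcurve(cfg.paths["curve"])
            dates = pd.read_csv(cfg.paths["dates"], sep="\t")
            diet = chrono.DietModel()
            rows = []
            for sample, grp in dates.groupby("sample_id", sort=True):
                ds = [chrono.RadiocarbonDate(r.uncal_bp, r.sigma,
                                             str(getattr(r, "lab_id", "")), sample)
                      for r in grp.itertuples()]
                if len(ds) > 1:
                    d, chi2, ok = chrono.combine_dates(ds)
                else:
                    d, chi2, ok = ds[0], 0.0, True
                cal = chrono.calibrate(d, curve)
                row = {"sample": sample, "uncal_bp": round(d.uncal_bp),
                       "sigma": round(d.sigma), "combined": len(ds) > 1,
                       "chi2": round(chi2, 2), "concordant": ok,
                       "Cal. BCE (95.4%)": chrono.format_bce_range(cal.hpd_954)}
                if "delta13c" in grp.columns and np.isfinite(grp["delta13c"].iloc[0]):
                    alpha = chrono.marine_fraction(float(grp["delta13c"].iloc[0]), diet)
                    corr = chrono.reservoir_correct(d, alpha, diet)
                    cal_rc = chrono.calibrate(corr, curve, reservoir_corrected=True)
                    row["marine_fraction"] = round(alpha, 3)
                    row["Cal. BCE rescorr (95.4%)"] = chrono.format_bce_range(
                        cal_rc.hpd_954)
                rows.append(row)
            report["chronology"] = pd.DataFrame(rows)
            report["status"]["chronology"] = "ok"
        except Exception as e:
            report["status"]["chronology"] = f"error: {e}"

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("qc", "sexcontam", "haplogroups", "coverage", "mds",
                    "admixture", "chronology"):
            if key in report and isinstance(report[key], pd.DataFrame):
                akio.write_table(report[key], outdir / f"{key}.tsv", meta)
        status = pd.DataFrame(sorted(report["status"].items()),
                              columns=["stage", "status"])
        akio.write_table(status, outdir / "status.tsv", meta)
    return report


def _load_panel(cfg: PipelineConfig):
    panel = akio.read_panel_vcf(cfg.paths["vcf"], cfg.paths["labels"])
    xs = Path(cfg.paths["vcf"]).with_suffix(".xsites.tsv")
    if xs.exists():
        panel.x_sites = pd.read_csv(xs, sep="\t")
    return panel


# ---------------------------------------------------------------------------
# simulation -> input bundle on disk


def write_simulation(sim_cfg, outdir: Path) -> dict:
    """Simulate a full dataset and write every pipeline input to ``outdir``.

    Returns the pipeline config dict (also written as ``pipeline.yaml``)
    pointing at the generated files.
    """
    from . import simulate as sim
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel, truth = sim.simulate_panel(sim_cfg)
    readsets, truth = sim.simulate_reads(sim_cfg, panel, truth)
    reference = sim.build_reference(sim_cfg)
    akio.write_fasta(reference, outdir / "reference.fasta")
    akio.write_panel_vcf(panel, outdir / "panel.vcf")
    akio.write_labels(panel, outdir / "labels.tsv")
    if panel.x_sites is not None:
        panel.x_sites.to_csv(outdir / "panel.xsites.tsv", sep="\t", index=False)
    akio.write_haplo_defs(truth.mt_defs, outdir / "mt_defs.nwk",
                          outdir / "mt_defs.tsv")
    akio.write_haplo_defs(truth.y_defs, outdir / "y_defs.nwk",
                          outdir / "y_defs.tsv")
    contam_seq = sim.haplotype_sequence(reference[sim.CHRMT],
                                        truth.mt_defs, truth.mt_defs.root)
    contam = list(contam_seq)
    for pos, base in truth.contaminant_mt.items():
        contam[pos - 1] = base
    akio.write_fasta({"contaminant1": "".join(contam)},
                     outdir / "mt_contaminants.fasta")
    sams, raw = {}, {}
    for sample, rs in sorted(readsets.items()):
        p = outdir / f"{sample}.sam"
        akio.write_sam(rs, p)
        sams[sample] = str(p)
        raw[sample] = truth.samples[sample].n_raw_total
    rows = [{"sample": s, "sex": t.sex, "contamination": t.contamination_fraction,
             "deamination_rate_5p": t.deamination_rate_5p,
             "deamination_decay": t.deamination_decay,
             "mt_haplogroup": t.mt_haplogroup, "y_haplogroup": t.y_haplogroup,
             "q": ",".join(f"{x:.4f}" for x in t.q),
             "n_raw_total": t.n_raw_total}
            for s, t in sorted(truth.samples.items())]
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    cfg = {
        "sam": sams, "raw_reads": raw, "seed": sim_cfg.seed,
        "paths": {
            "fasta": str(outdir / "reference.fasta"),
            "vcf": str(outdir / "panel.vcf"),
            "labels": str(outdir / "labels.tsv"),
            "mt_defs_newick": str(outdir / "mt_defs.nwk"),
            "mt_defs_variants": str(outdir / "mt_defs.tsv"),
            "y_defs_newick": str(outdir / "y_defs.nwk"),
            "y_defs_variants": str(outdir / "y_defs.tsv"),
            "mt_contaminants": str(outdir / "mt_contaminants.fasta"),
        },
    }
    with open(outdir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg
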