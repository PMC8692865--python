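"""End-to-end pipeline orchestration and report generation.

A :class:`RunConfig` carries an input VCF (or a simulation request), group
definitions (explicit table or inferred by the admixture stage), all stage
parameters with the published defaults, an output directory and one global
seed.  ``run_pipeline`` executes the stages in methods order — filter →
structure → diversity → differentiation → LD → sweeps — writing per-stage
TSVs, a provenance log, and a plain-text report whose sections mirror the
standard AMOVA / pairwise-differentiation / group-diversity / sweep-region
table shapes.

All stage seeds derive deterministically from the global seed, so a single
integer reproduces the full run byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differentiation, diversity, linkage, structure, \
    sweeps, variants
from .matrix import derive_seed
from .simulate import SimConfig, SweepSpec, simulate_genotypes, \
    write_fixture_vcf


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf: str | None = None
    simulate: dict | None = None          # SimConfig fields
    groups_file: str | None = None        # TSV: sample <tab> group
    infer_groups: bool = True
    infer_k: int = 3
    assign_threshold: float = 0.75
    min_maf: float = 0.05
    min_qual: float = 20.0
    min_depth: int = 10
    max_missing: float = 0.20
    final_min_depth: int = 15
    final_min_maf: float = 0.05
    ld_prune: bool = False
    ld_prune_window: int = 50
    ld_prune_step: int = 5
    ld_prune_r2: float = 0.2
    structure_k_min: int = 1
    structure_k_max: int = 5
    structure_replicates: int = 5
    pi_window: int = 1000
    amova_permutations: int = 999
    ld_max_dist: int = 200_000
    ld_threshold: float = 0.2
    sweep_ref_group: str | None = None
    sweep_query_group: str | None = None
    sweep_window: int = 50_000
    sweep_step: int = 10_000
    sweep_max_snps: int = 50
    sweep_top_fraction: float = 0.01
    sweep_gap: int = 10_000
    out_dir: str = "spinpop_out"
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_groups(path, sample_ids) -> dict[str, np.ndarray]:
    table = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(table.columns):
        raise ValueError("groups file needs 'sample' and 'group' columns")
    pos = {s: i for i, s in enumerate(sample_ids)}
    missing = [s for s in table["sample"] if s not in pos]
    if missing:
        raise ValueError(f"groups file names unknown samples: {missing[:5]}")
    out: dict[str, list[int]] = {}
    for s, g in zip(table["sample"], table["group"]):
        out.setdefault(str(g), []).append(pos[s])
    return {g: np.asarray(idx, int) for g, idx in sorted(out.items())}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a dict of stage outputs.

    Writes per-stage TSVs, ``provenance.json`` and ``report.txt`` under
    ``cfg.out_dir``.  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": cfg}
    log: list[dict] = []

    stage = "input"
    try:
        if cfg.simulate is not None:
            sim = dict(cfg.simulate)
            if "sweep" in sim and isinstance(sim["sweep"], dict):
                sim["sweep"] = SweepSpec(**sim["sweep"])
            if "chrom_lengths" in sim:
                sim["chrom_lengths"] = tuple(sim["chrom_lengths"])
            sim.setdefault("seed", derive_seed(cfg.seed, 0))
            simcfg = SimConfig(**sim)
            gm, truth = simulate_genotypes(simcfg)
            write_fixture_vcf(gm, simcfg, out / "input.vcf")
            gm = variants.read_vcf(out / "input.vcf")
            results["truth"] = truth
        elif cfg.vcf is not None:
            gm = variants.read_vcf(cfg.vcf)
        else:
            raise ValueError("config must give a VCF path or a simulation")
        log.append({"stage": stage, "n_samples": gm.n_samples,
                    "n_loci": gm.n_loci})

        stage = "filter"
        params = variants.FilterParams(
            min_maf=cfg.min_maf, min_qual=cfg.min_qual,
            min_depth=cfg.min_depth, max_site_missing=cfg.max_missing,
            max_sample_missing=cfg.max_missing,
            final_min_depth=cfg.final_min_depth,
            final_max_site_missing=cfg.max_missing,
            final_min_maf=cfg.final_min_maf)
        panel = variants.filter_cascade(gm, params)
        if cfg.ld_prune and panel.n_loci:
            panel = variants.ld_prune(gm, panel, cfg.ld_prune_window,
                                      cfg.ld_prune_step, cfg.ld_prune_r2)
        panel.provenance_table().to_csv(out / "filter_provenance.tsv",
                                        sep="\t", index=False)
        filtered = panel.extract(gm)
        variants.write_vcf(filtered, out / "filtered.vcf")
        variants.snp_density(gm, panel).to_csv(out / "snp_density.tsv",
                                               sep="\t", index=False)
        results["panel"] = panel
        results["filtered"] = filtered
        log.append({"stage": stage, "n_loci": panel.n_loci,
                    "n_samples": panel.n_samples})

        stage = "structure"
        sample_ids = filtered.samples["id"].tolist()
        if cfg.groups_file is not None and not cfg.infer_groups:
            groups = _load_groups(cfg.groups_file, sample_ids)
            results["structure"] = None
        else:
            logliks = {}
            fits = {}
            for k in range(cfg.structure_k_min, cfg.structure_k_max + 1):
                model = structure.AdmixtureModel(filtered, K=k)
                reps = model.fit_replicates(cfg.structure_replicates,
                                            seed=derive_seed(cfg.seed, 1, k))
                logliks[k] = [r.loglik for r in reps]
                fits[k] = max(reps, key=lambda r: r.loglik)
            pd.DataFrame([{"K": k, "replicate": i, "loglik": ll}
                          for k, lls in logliks.items()
                          for i, ll in enumerate(lls)]).to_csv(
                out / "loglik_by_k.tsv", sep="\t", index=False)
            if len(logliks) >= 3:
                dk = structure.evanno_delta_k(logliks)
                dk.to_csv(out / "delta_k.tsv", sep="\t", index=False)
                chosen = structure.best_k(dk)
            else:
                chosen = cfg.infer_k
            fit = fits[chosen]
            assign = fit.assign(cfg.assign_threshold)
            fit.q_table().merge(assign[["sample", "label"]],
                                on="sample").to_csv(out / "q_matrix.tsv",
                                                    sep="\t", index=False)
            groups = {}
            for lbl in sorted(assign["label"].unique()):
                if lbl == "admixed":
                    continue
                groups[lbl] = np.where(assign["label"] == lbl)[0]
            groups = {g: idx for g, idx in groups.items() if len(idx) >= 2}
            results["structure"] = fit
            results["chosen_k"] = chosen
            coords, explained = structure.pca(filtered)
            coords.to_csv(out / "pca.tsv", sep="\t", index=False)
        results["groups"] = groups
        log.append({"stage": stage, "groups":
                    {g: int(len(i)) for g, i in groups.items()}})

        stage = "diversity"
        div = diversity.group_summary(filtered, None, groups,
                                      window_bp=cfg.pi_window)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        diversity.locus_stats(filtered).to_csv(out / "locus_stats.tsv",
                                               sep="\t", index=False)
        results["diversity"] = div
        log.append({"stage": stage})

        stage = "differentiation"
        if len(groups) >= 2:
            am = differentiation.amova(filtered, None, groups,
                                       n_perm=cfg.amova_permutations,
                                       seed=derive_seed(cfg.seed, 2))
            pw = differentiation.differentiation_table(
                filtered, None, groups, n_perm=0,
                seed=derive_seed(cfg.seed, 3))
            am.table.to_csv(out / "amova.tsv", sep="\t", index=False)
            pw.to_csv(out / "pairwise_differentiation.tsv", sep="\t",
                      index=False)
            results["amova"] = am
            results["pairwise"] = pw
        log.append({"stage": stage})

        stage = "linkage"
        ld = linkage.ld_decay_summary(filtered, None, groups,
                                      max_dist=cfg.ld_max_dist,
                                      threshold=cfg.ld_threshold)
        ld.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        results["ld"] = ld
        log.append({"stage": stage})

        stage = "sweeps"
        ref, query = cfg.sweep_ref_group, cfg.sweep_query_group
        if ref is None or query is None:
            sized = sorted(groups, key=lambda g: -len(groups[g]))
            if len(sized) >= 2:
                ref, query = sized[0], sized[1]
        if (ref in groups and query in groups
                and len(groups[ref]) >= 5 and len(groups[query]) >= 5):
            windows = sweeps.scan(
                filtered, None, groups[ref], groups[query],
                size=cfg.sweep_window, step=cfg.sweep_step,
                max_snps=cfg.sweep_max_snps, seed=derive_seed(cfg.seed, 4))
            regions = sweeps.call_regions(
                windows, filtered.sites["pos"].to_numpy(),
                top_fraction=cfg.sweep_top_fraction, gap=cfg.sweep_gap)
            rt = sweeps.regions_table(regions)
            rt.to_csv(out / "sweep_regions.tsv", sep="\t", index=False)
            results["sweep_regions"] = rt
            results["sweep_pair"] = (ref, query)
        log.append({"stage": stage})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "provenance.json").write_text(json.dumps(
        {"version": __version__, "seed": cfg.seed,
         "config": dataclasses.asdict(cfg), "stages": log}, indent=2,
        default=str))
    (out / "report.txt").write_text(make_report(results))
    return results


def make_report(results: dict) -> str:
    """Plain-text report with AMOVA, pairwise, diversity and sweep
    sections."""
    lines = [f"spinpop {__version__} pipeline report", "=" * 40]
    panel = results.get("panel")
    if panel is not None:
        lines += ["", "Filter cascade", "-" * 20]
        for s in panel.provenance:
            lines.append(f"{s.name}: loci {s.loci_in} -> {s.loci_out}, "
                         f"samples {s.samples_in} -> {s.samples_out}")
    am = results.get("amova")
    if am is not None:
        lines += ["", "AMOVA (df, SS, Est. var., %, Fst, Nm, p)", "-" * 20]
        t = am.table
        nm = differentiation.gene_flow(am.phi) if am.phi > 0 else float(
            "inf")
        for _, r in t.iterrows():
            lines.append(f"{r['source']}: df={r['df']:.0f} SS={r['SS']:.2f} "
                         f"var={r['est_var']:.4f} pct={r['pct']:.1f}")
        lines.append(f"Fst(Phi)={am.phi:.4f} Nm={nm:.2f} "
                     f"p={am.p_value:.4f}")
    pw = results.get("pairwise")
    if pw is not None:
        lines += ["", "Pairwise differentiation (Fst, D, Id, Nm)", "-" * 20]
        for _, r in pw.iterrows():
            lines.append(f"{r['group_a']} vs {r['group_b']}: "
                         f"Fst={r['fst_phi']:.4f} D={r['nei_d']:.4f} "
                         f"Id={r['nei_id']:.4f} Nm={r['nm']:.2f}")
    div = results.get("diversity")
    if div is not None:
        lines += ["", "Group diversity (N, Na, Ne, h, uh, I, pi)", "-" * 20]
        for _, r in div.iterrows():
            lines.append(f"{r['group']}: N={r['n_samples']} "
                         f"Na={r['na']:.3f} Ne={r['ne']:.3f} h={r['h']:.3f} "
                         f"uh={r['uh']:.3f} I={r['i']:.3f} "
                         f"pi={r['pi']:.3e}")
    ld = results.get("ld")
    if ld is not None:
        lines += ["", "LD decay", "-" * 20]
        for _, r in ld.iterrows():
            lines.append(f"{r['group']}: decay at r2 threshold = "
                         f"{r['decay_bp']} bp ({r['n_pairs']} pairs)")
    lines += ["", "Selective sweep regions", "-" * 20]
    rt = results.get("sweep_regions")
    if rt is None or len(rt) == 0:
        lines.append("no regions at top 1%")
    else:
        ref, query = results.get("sweep_pair", ("?", "?"))
        lines.append(f"reference={ref} query={query}")
        for _, r in rt.iterrows():
            lines.append(f"{r['region']}: {r['chrom']}:{r['start']}-"
                         f"{r['stop']} snps={r['n_snps']} "
                         f"score={r['mean_score']:.3f}")
    return "\n".join(lines) + "\n"
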