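"""End-to-end orchestration: simulate (or load) -> preprocess -> differential
-> overlap/enrichment -> concordance -> network -> endpoints -> drugs.

Every stage writes one tabular artifact per figure-equivalent output with a
provenance header (stage name, thresholds, seed); a JSON run manifest
records the full configuration.  Re-running with the same config and seed
is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import differential as diff
from . import endpoints as endp
from . import enrichment as enr
from . import io
from . import network as net
from . import preprocess as prep
from .datatypes import ConfigurationError, TISSUES
from .simulate import SimConfig, StudyBundle, TruthManifest, generate_study

log = logging.getLogger("duomics")


@dataclass
class PipelineConfig:
    """Declarative configuration of the full cascade."""

    outdir: str = "results"
    input_dir: str | None = None          # load a written bundle instead of simulating
    simulate: SimConfig = field(default_factory=SimConfig)
    include_lipidome: bool = True

    # differential
    alpha_diff: float = 0.1
    top_k: int = 10

    # enrichment / drugs
    alpha_ora: float = 0.05
    min_hits: int = 2
    drug_top_k: int = 10

    # concordance
    rrho_step: int | None = None
    gsea_n_perm: int = 500
    gsea_weight: float = 1.0
    gsea_alpha: float = 0.1
    gsea_min_size: int = 5

    # network
    network_threshold: float = 0.85
    network_design: float = 0.1
    network_ncomp: int = 2
    network_keepx: int = 20
    network_prefilter: str = "variance"       # "variance" | "differential" | "none"
    network_prefilter_top: int = 100          # features kept per block (variance rule)
    network_component: dict = field(default_factory=lambda: {"liver": 1, "muscle": 2})

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", {})
        cfg = cls(**d)
        if isinstance(sim, dict):
            cfg.simulate = SimConfig(**sim)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# --------------------------------------------------------------------------
# bundle persistence
# --------------------------------------------------------------------------

def write_bundle(bundle: StudyBundle, outdir) -> None:
    outdir = Path(outdir)
    scales = {l.layer_id: l.scale for l in bundle.layers.values()}
    for key, layer in bundle.layers.items():
        io.write_matrix(layer, outdir / f"{key}.tsv")
    io.write_samples(bundle.samples, outdir / "samples.tsv")
    io.write_features(bundle.features, outdir / "features.tsv")
    for name, coll in bundle.collections.items():
        io.write_gmt(coll, outdir / f"{name}.gmt")
    bundle.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False,
                             lineterminator="\n")
    io.write_json(bundle.truth.to_json_dict(), outdir / "truth.json")
    io.write_json({"scales": scales}, outdir / "bundle_meta.json")


def read_bundle(indir) -> StudyBundle:
    indir = Path(indir)
    layer_specs = {
        "transcriptome": ("transcriptome", "raw_count"),
        "proteome": ("proteome", "log2"),
        "metabolome_c18": ("metabolome", "linear_peak"),
        "metabolome_amide": ("metabolome", "linear_peak"),
        "lipidome": ("lipidome", "linear_peak"),
    }
    layers = {}
    for key, (layer_id, scale) in layer_specs.items():
        path = indir / f"{key}.tsv"
        if path.exists():
            layers[key] = io.read_matrix(path, layer_id, scale)
    samples = io.read_samples(indir / "samples.tsv")
    features = io.read_features(indir / "features.tsv")
    collections = {}
    for gmt in sorted(indir.glob("*.gmt")):
        collections[gmt.stem] = io.read_gmt(gmt)
    phenotypes = pd.read_csv(indir / "phenotypes.tsv", sep="\t")
    truth = TruthManifest.from_json_dict(io.read_json(indir / "truth.json"))
    # validate every matrix column against the metadata
    for key, layer in layers.items():
        samples.for_samples(layer.sample_ids)
    return StudyBundle(layers, samples, features, collections, phenotypes, truth)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def run_preprocess(bundle: StudyBundle, cfg: PipelineConfig):
    """All four layer cascades; returns processed log2 layers keyed by
    layer name, voom weights, the PC:PE table and the reports."""
    out = {}
    reports = []
    ann = bundle.features.table

    tx, weights, rep = prep.preprocess_transcriptome(bundle.layers["transcriptome"], bundle.samples)
    out["transcriptome"] = tx
    reports.append(rep)

    pr, rep = prep.preprocess_proteome(bundle.layers["proteome"], bundle.samples)
    out["proteome"] = pr
    reports.append(rep)

    kegg = ann.loc[ann["layer_id"] == "metabolome", "kegg_present"].map(bool, na_action="ignore").fillna(False)
    mt, provenance, reps = prep.preprocess_metabolome(
        bundle.layers["metabolome_c18"], bundle.layers["metabolome_amide"],
        bundle.samples, kegg)
    out["metabolome"] = mt
    reports.extend(reps)

    ratios = None
    if cfg.include_lipidome:
        if "lipidome" not in bundle.layers:
            raise ConfigurationError("lipidome layer missing but PC:PE endpoint requested")
        cls = ann.loc[ann["layer_id"] == "lipidome", "lipid_class"]
        lp, ratios, rep = prep.preprocess_lipidome(bundle.layers["lipidome"], bundle.samples, cls)
        out["lipidome"] = lp
        reports.append(rep)
    return out, weights, ratios, reports


def run_differential(processed: dict, weights, bundle: StudyBundle,
                     cfg: PipelineConfig) -> dict:
    """One moderated differential table per layer x tissue."""
    results = {}
    for layer_name, layer in processed.items():
        for tissue in TISSUES:
            meta = bundle.samples.experimental(tissue)
            cols = [s for s in meta["sample_id"] if s in layer.values.columns]
            sub = layer.values[cols]
            groups = meta.set_index("sample_id").loc[cols, "group"]
            w = None
            if layer_name == "transcriptome" and weights is not None:
                w = weights[cols]
            model = diff.DifferentialAnalysis(sub, groups, weights=w,
                                              tissue=tissue, layer=layer_name)
            results[(layer_name, tissue)] = model.fit(alpha=cfg.alpha_diff, k=cfg.top_k)
    return results


def run_overlap(differentials: dict, layer: str) -> dict:
    """Per-direction Venn partitions for one layer."""
    liv = differentials[(layer, "liver")]
    mus = differentials[(layer, "muscle")]
    universe = frozenset(liv.table["feature_id"]) & frozenset(mus.table["feature_id"])
    out = {}
    for direction in ("up", "down"):
        out[direction] = enr.partition(
            [f for f in liv.called(direction) if f in universe],
            [f for f in mus.called(direction) if f in universe],
            universe, direction)
    return out


def _symbol_mapping(bundle: StudyBundle, layer: str) -> pd.Series:
    ann = bundle.features.table
    sub = ann[ann["layer_id"] == layer]
    return sub["gene_symbol"].astype("string").str.upper()


def run_enrichment(overlaps: dict, bundle: StudyBundle, cfg: PipelineConfig) -> pd.DataFrame:
    """ORA of each layer's partitions against its annotation source."""
    ann = bundle.features.table
    frames = []
    specs = []
    if "hallmark_like" in bundle.collections:
        coll = bundle.collections["hallmark_like"]
        specs.append(("transcriptome", coll, _symbol_mapping(bundle, "transcriptome")))
        specs.append(("proteome", coll, _symbol_mapping(bundle, "proteome")))
    met = ann[ann["layer_id"] == "metabolome"]
    if "super_pathway" in met.columns and met["super_pathway"].notna().any():
        coll = enr.build_class_collection("super_pathway", met["super_pathway"])
        specs.append(("metabolome", coll, pd.Series(met.index, index=met.index)))
    lip = ann[ann["layer_id"] == "lipidome"]
    if "lipid_class" in lip.columns and lip["lipid_class"].notna().any():
        coll = enr.build_class_collection("lipid_main_class", lip["lipid_class"])
        specs.append(("lipidome", coll, pd.Series(lip.index, index=lip.index)))
    for layer, coll, mapping in specs:
        if layer not in overlaps:
            continue
        res = enr.run_ora(enr.partitions_for_ora(overlaps[layer]), coll, mapping,
                          alpha=cfg.alpha_ora, min_hits=cfg.min_hits)
        res.insert(0, "layer", layer)
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_concordance(differentials: dict, bundle: StudyBundle, cfg: PipelineConfig,
                    seed: int):
    """RRHO and preranked GSEA per tissue on the gene/protein intersection."""
    gsym = _symbol_mapping(bundle, "transcriptome")
    psym = _symbol_mapping(bundle, "proteome")
    sets = {}
    if "hallmark_like" in bundle.collections:
        sets = {k: set(v) for k, v in bundle.collections["hallmark_like"].sets.items()}
    maps = {}
    gsea_results = {}
    paired_n = {}
    for tissue in TISSUES:
        paired = conc.intersect_layers(
            differentials[("transcriptome", tissue)].table,
            differentials[("proteome", tissue)].table, gsym, psym)
        paired_n[tissue] = len(paired)
        maps[tissue] = conc.rrho(paired["t_gene"], paired["t_protein"], step=cfg.rrho_step)
        if sets:
            for tag, col in (("G", "t_gene"), ("P", "t_protein")):
                gsea_results[(tissue, tag)] = conc.gsea_preranked(
                    paired[col], sets, weight=cfg.gsea_weight,
                    n_perm=cfg.gsea_n_perm, seed=seed, min_size=cfg.gsea_min_size,
                    alpha=cfg.gsea_alpha)
    heatmap = conc.cross_layer_heatmap(gsea_results, alpha=cfg.gsea_alpha) \
        if gsea_results else pd.DataFrame()
    return maps, gsea_results, heatmap, paired_n


def run_network(processed: dict, differentials: dict, bundle: StudyBundle,
                cfg: PipelineConfig) -> dict:
    """Per-tissue block sPLS-DA, relevance network, communities and hubs."""
    out = {}
    for tissue in TISSUES:
        meta = bundle.samples.experimental(tissue)
        blocks = {}
        for layer_name, layer in processed.items():
            cols = [s for s in meta["sample_id"] if s in layer.values.columns]
            sub = layer.values[cols]
            if cfg.network_prefilter == "variance":
                v = sub.var(axis=1).sort_values(ascending=False, kind="stable")
                sub = sub.loc[sub.index.isin(set(v.head(cfg.network_prefilter_top).index))]
            elif cfg.network_prefilter == "differential":
                tab = differentials[(layer_name, tissue)].table
                called = set(tab.loc[tab["direction"] != "ns", "feature_id"])
                sub = sub.loc[sub.index.isin(called)]
            elif cfg.network_prefilter != "none":
                raise ConfigurationError(f"unknown network_prefilter {cfg.network_prefilter!r}")
            if sub.shape[0] < 2:
                log.warning("%s/%s: too few features for network block; skipped",
                            tissue, layer_name)
                continue
            blocks[layer_name] = sub.T
        sample_ids = blocks[next(iter(blocks))].index
        groups = meta.set_index("sample_id").loc[sample_ids, "group"]
        keepx = {b: min(cfg.network_keepx, blocks[b].shape[1]) for b in blocks}
        model = net.BlockSPLSDA(blocks, groups, design=cfg.network_design).fit(
            ncomp=cfg.network_ncomp, keepX={b: [keepx[b]] * cfg.network_ncomp for b in blocks})
        component = cfg.network_component.get(tissue, 1)
        sims = net.relevance_similarity(model, component)
        directions = {}
        for (layer_name, t), res in differentials.items():
            if t == tissue:
                directions.update(dict(zip(res.table["feature_id"], res.table["direction"])))
        G = net.build_network(sims, threshold=cfg.network_threshold, directions=directions)
        membership, hubs = net.communities_and_hubs(G)
        out[tissue] = dict(model=model, graph=G, membership=membership,
                           hubs=hubs, component=component)
    return out


def run_endpoints(bundle: StudyBundle, ratios: pd.DataFrame | None) -> pd.DataFrame:
    """Phenotype endpoint comparisons, including the per-tissue PC:PE ratio."""
    phen = bundle.phenotypes.copy()
    variables = [c for c in phen.columns if c not in ("mouse", "group")]
    if ratios is not None:
        meta = bundle.samples.experimental()
        joined = ratios.join(meta.set_index("sample_id")[["tissue", "group"]], how="inner")
        for tissue in TISSUES:
            sub = joined[joined["tissue"] == tissue]
            col = f"{tissue}_pc_pe_ratio"
            per_mouse = sub.set_index(sub.index.str.replace(f"{tissue[:3]}_", "", regex=False))
            phen = phen.merge(per_mouse[["pc_pe_ratio"]].rename(columns={"pc_pe_ratio": col}),
                              left_on="mouse", right_index=True, how="left")
            variables.append(col)
    return endp.compare_table(phen.dropna(subset=variables), "group", variables)


def run_drugs(overlaps: dict, bundle: StudyBundle, cfg: PipelineConfig) -> pd.DataFrame:
    if "drug_signatures" not in bundle.collections:
        return pd.DataFrame()
    return enr.drug_repurposing(
        overlaps["transcriptome"], overlaps["proteome"],
        bundle.collections["drug_signatures"],
        _symbol_mapping(bundle, "transcriptome"), _symbol_mapping(bundle, "proteome"),
        alpha=cfg.alpha_ora, min_hits=cfg.min_hits, top_k=cfg.drug_top_k)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write all artifacts under
    ``cfg.outdir``.  Returns the in-memory results for programmatic use."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(cfg, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline_inner(cfg: PipelineConfig, outdir: Path) -> dict:
    seed = cfg.simulate.seed
    log.info("run starting with master seed %d", seed)

    if cfg.input_dir:
        bundle = read_bundle(cfg.input_dir)
    else:
        bundle = generate_study(cfg.simulate)
    write_bundle(bundle, outdir / "bundle")

    processed, weights, ratios, reports = run_preprocess(bundle, cfg)
    for layer_name, layer in processed.items():
        io.write_matrix(layer, outdir / "processed" / f"{layer_name}_log2.tsv")
    for rep in reports:
        io.write_table(rep.to_frame(), outdir / "processed" / f"report_{rep.layer}.tsv",
                       provenance={"stage": "preprocess", "layer": rep.layer,
                                   "qc_cv_before": rep.qc_cv_before,
                                   "qc_cv_after": rep.qc_cv_after})
    if ratios is not None:
        io.write_table(ratios.reset_index(), outdir / "processed" / "pc_pe_ratios.tsv",
                       provenance={"stage": "preprocess"})

    differentials = run_differential(processed, weights, bundle, cfg)
    for (layer_name, tissue), res in differentials.items():
        io.write_table(res.table, outdir / "differential" / f"{layer_name}_{tissue}.tsv",
                       provenance={"stage": "differential", "alpha": cfg.alpha_diff,
                                   "prior_df": round(res.prior_df, 4)})

    overlaps = {}
    venn = {}
    for layer_name in processed:
        overlaps[layer_name] = run_overlap(differentials, layer_name)
        venn[layer_name] = {d: p.counts() for d, p in overlaps[layer_name].items()}
    io.write_json(venn, outdir / "overlap" / "venn_counts.json")

    ora = run_enrichment(overlaps, bundle, cfg)
    io.write_table(ora, outdir / "enrichment" / "ora.tsv",
                   provenance={"stage": "enrichment", "alpha": cfg.alpha_ora,
                               "min_hits": cfg.min_hits})

    maps, gsea_results, heatmap, paired_n = run_concordance(differentials, bundle, cfg, seed)
    for tissue, m in maps.items():
        df = pd.DataFrame(m.signed_log_p_adj, index=m.thresholds, columns=m.thresholds)
        df.index.name = "rank_cutoff"
        io.write_table(df.reset_index(), outdir / "concordance" / f"rrho_{tissue}.tsv",
                       provenance={"stage": "concordance", "step": m.step,
                                   "n_paired": paired_n[tissue]})
    for (tissue, tag), res in gsea_results.items():
        io.write_table(res, outdir / "concordance" / f"gsea_{tissue}_{tag}.tsv",
                       provenance={"stage": "concordance", "n_perm": cfg.gsea_n_perm,
                                   "seed": seed})
    io.write_table(heatmap, outdir / "concordance" / "cross_layer.tsv",
                   provenance={"stage": "concordance", "alpha": cfg.gsea_alpha})

    networks = run_network(processed, differentials, bundle, cfg)
    for tissue, resd in networks.items():
        G = resd["graph"]
        edges = pd.DataFrame(
            [dict(source=u, target=v, similarity=d["similarity"])
             for u, v, d in sorted(G.edges(data=True))])
        nodes = pd.DataFrame(
            [dict(feature_id=n, block=d.get("block"), direction=d.get("direction"),
                  community=resd["membership"].get(n))
             for n, d in sorted(G.nodes(data=True))])
        prov = {"stage": "network", "threshold": cfg.network_threshold,
                "component": resd["component"], "ncomp": cfg.network_ncomp,
                "keepx": cfg.network_keepx, "prefilter": cfg.network_prefilter}
        io.write_table(edges, outdir / "network" / f"edges_{tissue}.tsv", provenance=prov)
        io.write_table(nodes, outdir / "network" / f"nodes_{tissue}.tsv", provenance=prov)
        io.write_table(resd["hubs"], outdir / "network" / f"hubs_{tissue}.tsv", provenance=prov)

    endpoints_table = run_endpoints(bundle, ratios)
    io.write_table(endpoints_table, outdir / "endpoints" / "endpoints.tsv",
                   provenance={"stage": "endpoints", "alpha": 0.05})

    drugs = run_drugs(overlaps, bundle, cfg)
    io.write_table(drugs, outdir / "drugs" / "drug_repurposing.tsv",
                   provenance={"stage": "drugs", "alpha": cfg.alpha_ora,
                               "min_hits": cfg.min_hits, "top_k": cfg.drug_top_k})

    manifest_cfg = {k: v for k, v in cfg.to_dict().items()
                    if k not in ("outdir", "input_dir")}  # paths are environmental
    io.write_json({"config": manifest_cfg, "seed": seed,
                   "stages": ["preprocess", "differential", "overlap", "enrichment",
                              "concordance", "network", "endpoints", "drugs"]},
                  outdir / "manifest.json")
    log.info("run complete")
    return dict(bundle=bundle, processed=processed, weights=weights, ratios=ratios,
                reports=reports, differentials=differentials, overlaps=overlaps,
                ora=ora, rrho=maps, gsea=gsea_results, heatmap=heatmap,
                networks=networks, endpoints=endpoints_table, drugs=drugs)
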