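"""Synthetic two-tissue, four-layer alcohol study with known ground truth.

The generator emulates the statistical structure of a chronic-alcohol mouse
study: two tissues (liver, skeletal muscle) sampled from the same animals
(control n=9, alcohol n=14), with

* a transcriptome of negative-binomial gene counts,
* a proteome of log2 intensities with intensity-dependent (MNAR) plus
  completely-at-random missingness,
* a metabolome acquired on two chromatography columns with partially
  overlapping feature coverage, pooled-QC injections and multiplicative
  injection-order drift,
* a lipidome with annotated main classes, missing values, pooled QCs and
  drift, plus a planted phosphatidylcholine:phosphatidylethanolamine class
  shift (ratio up in alcohol muscle, down in alcohol liver),

together with planted tissue-specific / shared / null differential features,
one cross-layer correlated module driven by a single latent group-separating
factor, planted-and-decoy gene-set and drug-signature collections, and a
small end-point phenotype table.  Everything the generator does is recorded
in a :class:`TruthManifest` so downstream stages can be tested by recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationCollection,
    ConfigurationError,
    FeatureAnnotation,
    OmicsLayer,
    SampleMeta,
)

DEFAULT_LIPID_CLASSES = {
    "PC": 0.28,
    "PE": 0.20,
    "TG": 0.14,
    "PI": 0.08,
    "PS": 0.07,
    "SM": 0.08,
    "LPC": 0.06,
    "PEt": 0.05,
    "Cer": 0.04,
}

METAB_SUPER_PATHWAYS = (
    "Amino acid",
    "Carbohydrate",
    "Lipid",
    "Nucleotide",
    "Cofactors and vitamins",
    "Energy",
    "Xenobiotics",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions every recovery test runs under: the
    real design's group sizes (9 control vs 14 alcohol), desk-scale feature
    counts roughly one tenth of the real layers, and noise/effect levels
    typical of bulk RNA-seq counts and MS peak intensities.
    """

    # design
    n_control: int = 9
    n_alcohol: int = 14
    n_genes: int = 2000
    n_proteins: int = 800
    n_metabolites: int = 300
    n_lipids: int = 300

    # planted differential structure (fractions of each layer)
    frac_liver: float = 0.05
    frac_muscle: float = 0.05
    frac_shared: float = 0.02
    lfc_low: float = 1.0
    lfc_high: float = 2.5

    # transcriptome count model
    lib_size_low: float = 8e5
    lib_size_high: float = 1.2e6
    nb_dispersion: float = 0.1

    # intensity model (log2) for proteome / metabolome / lipidome
    intensity_mean: float = 17.0
    intensity_sd: float = 2.0
    protein_noise_sd: float = 0.5
    intensity_noise_sd: float = 0.6

    # proteome / lipidome missingness
    mnar_center_sd: float = 1.8   # missingness midpoint = mean - this * sd
    mnar_width: float = 0.6
    mcar_rate: float = 0.02

    # QC injections and drift (metabolome + lipidome)
    qc_every: int = 4
    qc_noise_sd: float = 0.05
    drift_kind: str = "linear"
    drift_amplitude: float = 0.2  # total relative drift over one run

    # metabolome columns
    metab_frac_a_only: float = 0.4
    metab_frac_b_only: float = 0.3
    kegg_frac: float = 0.8

    # lipidome classes and planted PC:PE shift (log2 per class)
    lipid_class_fracs: dict = field(default_factory=lambda: dict(DEFAULT_LIPID_CLASSES))
    pcpe_shift_log2: float = 0.4

    # planted cross-layer module (single latent factor).  The factor both
    # separates the groups (delta) and varies within groups (latent_sd), so
    # the module is a genuine correlation structure over and above the
    # group contrast — the situation a second latent component must find.
    module_tissue: str = "muscle"
    module_sizes: dict = field(
        default_factory=lambda: {"transcriptome": 16, "proteome": 10, "metabolome": 6, "lipidome": 8}
    )
    module_loading: float = 0.95
    module_noise_sd: float = 0.2
    module_group_delta: float = 2.0
    module_latent_sd: float = 3.0

    # annotation / drug collections
    planted_set_size: int = 15
    n_decoy_sets: int = 30
    drug_target_size: int = 20
    n_decoy_drugs: int = 40

    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_liver", "frac_muscle", "frac_shared"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.frac_liver + self.frac_muscle + self.frac_shared > 0.9:
            raise ConfigurationError("planted fractions exceed available features")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.qc_every < 1:
            raise ConfigurationError("qc_every must be >= 1")
        if self.drift_amplitude < 0:
            raise ConfigurationError("drift_amplitude must be >= 0")
        for layer, size in self.module_sizes.items():
            n = {"transcriptome": self.n_genes, "proteome": self.n_proteins,
                 "metabolome": self.n_metabolites, "lipidome": self.n_lipids}[layer]
            if size > n:
                raise ConfigurationError(f"module size {size} exceeds {layer} width {n}")
        if abs(sum(self.lipid_class_fracs.values()) - 1.0) > 1e-6:
            raise ConfigurationError("lipid class fractions must sum to 1")


@dataclass
class TruthManifest:
    """Exact record of the generating process, for recovery tests."""

    features: dict          # layer -> records of per-feature truth
    module: dict            # tissue, members per layer, loading, noise, delta
    drift: dict             # batch -> {kind, rate}
    pcpe_shift: dict        # tissue -> log2 shift applied to PC (PE gets -shift)
    planted_sets: list      # names of truly enriched annotation sets
    planted_drugs: list     # names of truly matching drug signatures
    phenotype_effects: dict # variable -> description of planted shift
    config: dict

    def feature_frame(self, layer: str) -> pd.DataFrame:
        return pd.DataFrame(self.features[layer]).set_index("feature_id", drop=False)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthManifest":
        return cls(**d)


@dataclass
class StudyBundle:
    """Everything :func:`generate_study` produces."""

    layers: dict            # key -> OmicsLayer ("metabolome_c18" etc.)
    samples: SampleMeta
    features: FeatureAnnotation
    collections: dict       # name -> AnnotationCollection
    phenotypes: pd.DataFrame
    truth: TruthManifest


def generate_qc_drift(order, kind: str = "linear", rate: float = 0.01) -> np.ndarray:
    """Multiplicative drift factor per injection.

    ``linear``: factor = 1 + rate * order; ``exponential``: exp(rate * order).
    Rate 0 yields all-ones.  A parameterization producing non-positive
    factors is a configuration error.
    """
    order = np.asarray(order, dtype=float)
    if kind == "linear":
        factors = 1.0 + rate * order
    elif kind == "exponential":
        factors = np.exp(rate * order)
    else:
        raise ConfigurationError(f"unknown drift kind {kind!r}")
    if (factors <= 0).any():
        raise ConfigurationError("drift parameterization yields non-positive factors")
    return factors


def _plant_effects(rng, n: int, cfg: SimConfig):
    """Assign each feature a truth category and per-tissue log2 effects."""
    n_liv = int(round(cfg.frac_liver * n))
    n_mus = int(round(cfg.frac_muscle * n))
    n_sha = int(round(cfg.frac_shared * n))
    idx = rng.permutation(n)
    cat = np.array(["null"] * n, dtype=object)
    cat[idx[:n_liv]] = "liver"
    cat[idx[n_liv:n_liv + n_mus]] = "muscle"
    cat[idx[n_liv + n_mus:n_liv + n_mus + n_sha]] = "shared"
    mag = rng.uniform(cfg.lfc_low, cfg.lfc_high, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    lfc = mag * sign
    lfc_liver = np.where(np.isin(cat, ["liver", "shared"]), lfc, 0.0)
    lfc_muscle = np.where(np.isin(cat, ["muscle", "shared"]), lfc, 0.0)
    return cat, lfc_liver, lfc_muscle


def _injection_schedule(exp_ids: list[str], qc_every: int, rng) -> pd.DataFrame:
    """Randomized autosampler sequence shared by every LC-MS run: a QC at the
    start, one every ``qc_every`` experimental injections, and one at the
    end.  QC sample ids are shared across runs (each run measures its own
    pooled aliquot under the same schedule)."""
    order_ids = list(rng.permutation(exp_ids))
    rows = []
    pos = 0
    qc_i = 0

    def add_qc():
        nonlocal pos, qc_i
        pos += 1
        qc_i += 1
        rows.append((f"QC{qc_i:02d}", "qc", pos))

    add_qc()
    for i, sid in enumerate(order_ids):
        pos += 1
        rows.append((sid, "experimental", pos))
        if (i + 1) % qc_every == 0 and i + 1 < len(order_ids):
            add_qc()
    add_qc()
    return pd.DataFrame(rows, columns=["sample_id", "role", "injection_order"])


def generate_study(cfg: SimConfig) -> StudyBundle:
    """Generate the full synthetic study bundle (deterministic in cfg.seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    mice = [f"C{i:02d}" for i in range(1, cfg.n_control + 1)] + \
           [f"A{i:02d}" for i in range(1, cfg.n_alcohol + 1)]
    groups = ["control"] * cfg.n_control + ["alcohol"] * cfg.n_alcohol
    tissues = ("liver", "muscle")
    samples = {t: [f"{t[:3]}_{m}" for m in mice] for t in tissues}
    all_exp = samples["liver"] + samples["muscle"]
    group_of = {}
    tissue_of = {}
    for t in tissues:
        for sid, g in zip(samples[t], groups):
            group_of[sid] = g
            tissue_of[sid] = t
    is_alcohol = {sid: group_of[sid] == "alcohol" for sid in all_exp}

    # ---- feature spaces ---------------------------------------------------
    gene_ids = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    gene_symbols = [f"GENE{i:04d}" for i in range(1, cfg.n_genes + 1)]
    prot_ids = [f"P{i:04d}" for i in range(1, cfg.n_proteins + 1)]
    # proteins map 1:1 onto the first n_proteins genes
    prot_symbols = gene_symbols[: cfg.n_proteins]
    met_ids = [f"M{i:04d}" for i in range(1, cfg.n_metabolites + 1)]
    lip_ids = [f"L{i:04d}" for i in range(1, cfg.n_lipids + 1)]

    # lipid classes by configured composition
    classes = list(cfg.lipid_class_fracs)
    counts = np.floor(np.array([cfg.lipid_class_fracs[c] for c in classes]) * cfg.n_lipids).astype(int)
    while counts.sum() < cfg.n_lipids:
        counts[int(np.argmax([cfg.lipid_class_fracs[c] for c in classes]))] += 1
    lipid_class = np.repeat(classes, counts)[: cfg.n_lipids]
    rng.shuffle(lipid_class)

    kegg_present = rng.random(cfg.n_metabolites) < cfg.kegg_frac
    met_pathway = rng.choice(METAB_SUPER_PATHWAYS, size=cfg.n_metabolites)

    # ---- truth: planted differential effects ------------------------------
    truth_features: dict[str, list] = {}
    effects = {}
    for layer, ids in (
        ("transcriptome", gene_ids),
        ("metabolome", met_ids),
        ("lipidome", lip_ids),
    ):
        cat, lfc_l, lfc_m = _plant_effects(rng, len(ids), cfg)
        effects[layer] = (cat, lfc_l, lfc_m)
    # proteome inherits (attenuated) effects from its parent genes so the
    # two layers are genuinely concordant, as in paired bulk data
    g_cat, g_lfc_l, g_lfc_m = effects["transcriptome"]
    p_slice = slice(0, cfg.n_proteins)
    effects["proteome"] = (
        g_cat[p_slice].copy(),
        0.8 * g_lfc_l[p_slice],
        0.8 * g_lfc_m[p_slice],
    )

    # ---- abundance baselines (drawn before module placement so module
    # members can be required to be reliably measured features) ------------
    base_log2 = rng.normal(4.0, 2.0, size=cfg.n_genes)           # relative log2 abundance
    tissue_offset = rng.normal(0.0, 1.0, size=cfg.n_genes)       # liver-vs-muscle shift
    lip_base = rng.normal(cfg.intensity_mean, cfg.intensity_sd, size=cfg.n_lipids)

    # ---- cross-layer module ----------------------------------------------
    layer_ids_map = {"transcriptome": gene_ids, "proteome": prot_ids,
                     "metabolome": met_ids, "lipidome": lip_ids}
    module_members: dict[str, list] = {}
    module_mask: dict[str, np.ndarray] = {}
    for layer, ids in layer_ids_map.items():
        cat = effects[layer][0]
        eligible = cat == "null"
        if layer == "metabolome":
            # module metabolites must carry a KEGG ID to remain observable
            eligible = eligible & kegg_present
        elif layer == "transcriptome":
            # module transcripts are expressed well above the filter floor
            eligible = eligible & (base_log2 > np.quantile(base_log2, 0.4))
        elif layer == "lipidome":
            # module lipids sit above the intensity range where peaks go
            # missing, and outside PC/PE so the module and the class-shift
            # endpoint remain independently testable ground truths
            eligible = eligible & (lip_base > cfg.intensity_mean - cfg.intensity_sd) \
                & ~np.isin(lipid_class, ["PC", "PE"])
        null_pos = np.flatnonzero(eligible)
        take = rng.choice(null_pos, size=cfg.module_sizes[layer], replace=False)
        mask = np.zeros(len(ids), dtype=bool)
        mask[take] = True
        module_mask[layer] = mask
        module_members[layer] = [ids[i] for i in sorted(take)]

    mt = cfg.module_tissue
    latent = {}
    for sid in samples[mt]:
        latent[sid] = cfg.module_group_delta * float(is_alcohol[sid]) \
            + rng.normal(0.0, cfg.module_latent_sd)

    def module_signal(layer: str, sample_id: str) -> np.ndarray:
        """Additive log2 contribution of the latent module factor."""
        out = np.zeros(len(layer_ids_map[layer]))
        if tissue_of.get(sample_id) == mt:
            u = latent[sample_id]
            m = module_mask[layer]
            out[m] = cfg.module_loading * u + rng.normal(0.0, cfg.module_noise_sd, size=m.sum())
        return out

    # ---- transcriptome counts --------------------------------------------
    lib_sizes = rng.uniform(cfg.lib_size_low, cfg.lib_size_high, size=len(all_exp))
    counts_mat = np.zeros((cfg.n_genes, len(all_exp)))
    g_lfc = {"liver": g_lfc_l, "muscle": g_lfc_m}
    for j, sid in enumerate(all_exp):
        t = tissue_of[sid]
        log2_mu = base_log2 + (tissue_offset if t == "liver" else 0.0)
        if is_alcohol[sid]:
            log2_mu = log2_mu + g_lfc[t]
        log2_mu = log2_mu + module_signal("transcriptome", sid)
        rel = 2.0 ** log2_mu
        mu = rel / rel.sum() * lib_sizes[j]
        # NB via gamma-Poisson mixture, dispersion = 1/size
        size = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape=size, scale=mu / size)
        counts_mat[:, j] = rng.poisson(lam)
    transcriptome = OmicsLayer(
        "transcriptome", pd.DataFrame(counts_mat, index=gene_ids, columns=all_exp), "raw_count"
    )

    # ---- proteome (log2 with MNAR + MCAR missingness) ---------------------
    p_base = rng.normal(cfg.intensity_mean, cfg.intensity_sd, size=cfg.n_proteins)
    p_tissue = rng.normal(0.0, 0.8, size=cfg.n_proteins)
    _, p_lfc_l, p_lfc_m = effects["proteome"]
    p_lfc = {"liver": p_lfc_l, "muscle": p_lfc_m}
    prot_mat = np.zeros((cfg.n_proteins, len(all_exp)))
    for j, sid in enumerate(all_exp):
        t = tissue_of[sid]
        mu = p_base + (p_tissue if t == "liver" else 0.0)
        if is_alcohol[sid]:
            mu = mu + p_lfc[t]
        mu = mu + module_signal("proteome", sid)
        prot_mat[:, j] = mu + rng.normal(0.0, cfg.protein_noise_sd, size=cfg.n_proteins)
    tau = cfg.intensity_mean - cfg.mnar_center_sd * cfg.intensity_sd
    p_mnar = 1.0 / (1.0 + np.exp((prot_mat - tau) / cfg.mnar_width))
    miss = (rng.random(prot_mat.shape) < p_mnar) | (rng.random(prot_mat.shape) < cfg.mcar_rate)
    prot_vals = np.where(miss, np.nan, prot_mat)
    proteome = OmicsLayer(
        "proteome", pd.DataFrame(prot_vals, index=prot_ids, columns=all_exp), "log2"
    )

    # ---- metabolome / lipidome helper -------------------------------------
    sched = _injection_schedule(all_exp, cfg.qc_every, rng)
    n_inj = len(sched)

    def intensity_run(layer: str, ids: list[str], feat_pos: np.ndarray,
                      extra_shift, with_missing: bool, baselines=None):
        """One LC-MS run on the shared schedule: experimental + QC
        injections, multiplicative drift, linear peak-area scale.

        ``extra_shift(sample_id)`` returns an additive log2 vector over the
        full layer (class shifts, module signal).  QCs are noisy copies of
        the pooled mean profile, as pooled-supernatant QCs are.
        """
        if baselines is None:
            base = rng.normal(cfg.intensity_mean, cfg.intensity_sd, size=len(feat_pos))
        else:
            base = np.asarray(baselines)[feat_pos]
        cat, lfc_l, lfc_m = effects[layer]
        lfc = {"liver": lfc_l[feat_pos], "muscle": lfc_m[feat_pos]}
        t_off = rng.normal(0.0, 0.8, size=len(feat_pos))
        log2_true = {}
        for sid in all_exp:
            t = tissue_of[sid]
            mu = base + (t_off if t == "liver" else 0.0)
            if is_alcohol[sid]:
                mu = mu + lfc[t]
            mu = mu + extra_shift(sid)[feat_pos]
            log2_true[sid] = mu
        pooled = np.mean([log2_true[sid] for sid in all_exp], axis=0)
        rate = _drift_rate(cfg, n_inj)
        factors = generate_qc_drift(sched["injection_order"].to_numpy(), cfg.drift_kind, rate)
        cols = {}
        for (_, row), f in zip(sched.iterrows(), factors):
            sid = row["sample_id"]
            if row["role"] == "qc":
                x = pooled + rng.normal(0.0, cfg.qc_noise_sd, size=len(feat_pos))
            else:
                x = log2_true[sid] + rng.normal(0.0, cfg.intensity_noise_sd, size=len(feat_pos))
            lin = (2.0 ** x) * f
            if with_missing:
                pm = 1.0 / (1.0 + np.exp((x - tau) / cfg.mnar_width))
                m = (rng.random(len(x)) < pm) | (rng.random(len(x)) < cfg.mcar_rate)
                lin = np.where(m, np.nan, lin)
            cols[sid] = lin
        run_ids = [ids[i] for i in feat_pos]
        mat = pd.DataFrame(cols, index=run_ids)
        mat = mat[list(sched["sample_id"])]
        return mat, rate

    # metabolome column coverage
    n_m = cfg.n_metabolites
    r = rng.random(n_m)
    a_only = r < cfg.metab_frac_a_only
    b_only = (r >= cfg.metab_frac_a_only) & (r < cfg.metab_frac_a_only + cfg.metab_frac_b_only)
    both = ~(a_only | b_only)
    pos_a = np.flatnonzero(a_only | both)
    pos_b = np.flatnonzero(b_only | both)

    met_mod = lambda sid: module_signal("metabolome", sid)
    met_a, rate_a = intensity_run("metabolome", met_ids, pos_a, met_mod, False)
    met_b, rate_b = intensity_run("metabolome", met_ids, pos_b, met_mod, False)

    # lipidome: class-level PC:PE shift on top of per-feature effects
    pc_mask = lipid_class == "PC"
    pe_mask = lipid_class == "PE"
    pcpe_shift = {"muscle": cfg.pcpe_shift_log2, "liver": -cfg.pcpe_shift_log2}

    def lip_shift(sid):
        out = module_signal("lipidome", sid)
        if is_alcohol[sid]:
            s = pcpe_shift[tissue_of[sid]]
            out = out + np.where(pc_mask, s, 0.0) + np.where(pe_mask, -s, 0.0)
        return out

    lip_mat, rate_l = intensity_run(
        "lipidome", lip_ids, np.arange(cfg.n_lipids), lip_shift, True, baselines=lip_base
    )

    metabolome_a = OmicsLayer("metabolome", met_a, "linear_peak")
    metabolome_b = OmicsLayer("metabolome", met_b, "linear_peak")
    lipidome = OmicsLayer("lipidome", lip_mat, "linear_peak")

    # ---- sample metadata ---------------------------------------------------
    inj_of = dict(zip(sched["sample_id"], sched["injection_order"]))
    rows = []
    for sid in all_exp:
        rows.append(dict(sample_id=sid, tissue=tissue_of[sid], group=group_of[sid],
                         role="experimental", injection_order=int(inj_of[sid]), batch="lcms"))
    for _, row in sched.iterrows():
        if row["role"] == "qc":
            rows.append(dict(sample_id=row["sample_id"], tissue=np.nan, group=np.nan,
                             role="qc", injection_order=int(row["injection_order"]), batch="lcms"))
    sample_meta = SampleMeta(pd.DataFrame(rows))

    # ---- feature annotations ----------------------------------------------
    ann_rows = []
    for fid, sym in zip(gene_ids, gene_symbols):
        ann_rows.append(dict(feature_id=fid, display_name=sym, layer_id="transcriptome",
                             gene_symbol=sym))
    for fid, sym in zip(prot_ids, prot_symbols):
        ann_rows.append(dict(feature_id=fid, display_name=sym.capitalize(), layer_id="proteome",
                             gene_symbol=sym))
    for i, fid in enumerate(met_ids):
        ann_rows.append(dict(feature_id=fid, display_name=f"metabolite_{i+1}",
                             layer_id="metabolome", super_pathway=met_pathway[i],
                             kegg_present=bool(kegg_present[i])))
    for i, fid in enumerate(lip_ids):
        ann_rows.append(dict(feature_id=fid, display_name=f"{lipid_class[i]}({i+1})",
                             layer_id="lipidome", lipid_class=lipid_class[i]))
    annotations = FeatureAnnotation(pd.DataFrame(ann_rows))

    # ---- annotation + drug collections ------------------------------------
    sym_arr = np.array(gene_symbols)
    planted_sets = {}
    planted_drugs = {}
    for tissue, lfc_vec in (("LIVER", g_lfc_l), ("MUSCLE", g_lfc_m)):
        for direction, m in (("UP", lfc_vec > 0), ("DOWN", lfc_vec < 0)):
            pool = np.flatnonzero(m)
            if len(pool) >= cfg.planted_set_size:
                take = rng.choice(pool, size=cfg.planted_set_size, replace=False)
                planted_sets[f"SET_{tissue}_{direction}"] = sorted(sym_arr[take])
            if len(pool) >= cfg.drug_target_size:
                take = rng.choice(pool, size=cfg.drug_target_size, replace=False)
                planted_drugs[f"DRUG_{tissue}_{direction}"] = sorted(sym_arr[take])
    gene_sets = dict(planted_sets)
    for i in range(cfg.n_decoy_sets):
        take = rng.choice(cfg.n_genes, size=cfg.planted_set_size, replace=False)
        gene_sets[f"DECOY_SET_{i+1:02d}"] = sorted(sym_arr[take])
    drug_sets = dict(planted_drugs)
    for i in range(cfg.n_decoy_drugs):
        take = rng.choice(cfg.n_genes, size=cfg.drug_target_size, replace=False)
        drug_sets[f"DECOY_DRUG_{i+1:02d}"] = sorted(sym_arr[take])
    collections = {
        "hallmark_like": AnnotationCollection("hallmark_like",
                                              {k: frozenset(v) for k, v in gene_sets.items()}),
        "drug_signatures": AnnotationCollection("drug_signatures",
                                                {k: frozenset(v) for k, v in drug_sets.items()}),
    }

    # ---- endpoint phenotypes ----------------------------------------------
    phen_effects = {
        "body_mass_g": (28.0, 2.0, -2.0),
        "lean_mass_g": (21.0, 1.5, -1.5),
        "fat_mass_g": (4.5, 1.0, 0.8),
        "muscle_mass_mg": (170.0, 12.0, -20.0),
        "muscle_torque_mNm": (230.0, 20.0, -30.0),
        "liver_mass_g": (1.10, 0.12, 0.0),
    }
    phen = {"mouse": mice, "group": groups}
    for var, (mu, sd, shift) in phen_effects.items():
        vals = rng.normal(mu, sd, size=len(mice))
        vals = vals + np.where(np.array(groups) == "alcohol", shift, 0.0)
        phen[var] = np.round(vals, 3)
    # blood alcohol: control sits at the detection limit (zero-inflated),
    # alcohol is log-normal -- a clearly non-normal endpoint
    trace = np.where(rng.random(len(mice)) < 0.25,
                     rng.uniform(0.5, 3.0, size=len(mice)), 0.0)
    bac = np.where(np.array(groups) == "alcohol",
                   rng.lognormal(mean=np.log(80.0), sigma=0.5, size=len(mice)),
                   trace)
    phen["blood_alcohol_mg_dl"] = np.round(bac, 3)
    phenotypes = pd.DataFrame(phen)

    # ---- truth manifest ----------------------------------------------------
    for layer, ids in layer_ids_map.items():
        cat, lfc_l, lfc_m = effects[layer]
        recs = []
        for i, fid in enumerate(ids):
            recs.append(dict(feature_id=fid, category=str(cat[i]),
                             lfc_liver=float(lfc_l[i]), lfc_muscle=float(lfc_m[i]),
                             in_module=bool(module_mask[layer][i])))
        truth_features[layer] = recs
    truth = TruthManifest(
        features=truth_features,
        module=dict(tissue=mt, members=module_members, loading=cfg.module_loading,
                    noise_sd=cfg.module_noise_sd, group_delta=cfg.module_group_delta),
        drift={"metabolome_c18": dict(kind=cfg.drift_kind, rate=float(rate_a)),
               "metabolome_amide": dict(kind=cfg.drift_kind, rate=float(rate_b)),
               "lipidome": dict(kind=cfg.drift_kind, rate=float(rate_l))},
        pcpe_shift={k: float(v) for k, v in pcpe_shift.items()},
        planted_sets=sorted(planted_sets),
        planted_drugs=sorted(planted_drugs),
        phenotype_effects={k: dict(control_mean=v[0], sd=v[1], alcohol_shift=v[2])
                           for k, v in phen_effects.items()},
        config=dataclasses.asdict(cfg),
    )

    layers = {
        "transcriptome": transcriptome,
        "proteome": proteome,
        "metabolome_c18": metabolome_a,
        "metabolome_amide": metabolome_b,
        "lipidome": lipidome,
    }
    return StudyBundle(layers, sample_meta, annotations, collections, phenotypes, truth)


def _drift_rate(cfg: SimConfig, n_injections: int) -> float:
    """Per-injection drift rate giving the configured total relative drift."""
    if cfg.drift_amplitude == 0:
        return 0.0
    if cfg.drift_kind == "linear":
        return cfg.drift_amplitude / n_injections
    return np.log1p(cfg.drift_amplitude) / n_injections
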