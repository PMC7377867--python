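"""Synthetic multi-omic melanoma-like cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a small number of latent subtypes; a planted set of genes whose
expression follows copy-number dosage (positive effect); a planted set whose
expression is repressed by promoter methylation (negative effect); per-sample
coupling between the copy-number and methylation abnormality burdens;
subtype-dependent survival hazards and mutation frequencies. Every planted
quantity is returned as ground truth so each pipeline stage has a
parameter-recovery test.

Copy number is generated at segment level over a toy genome (so
segment-to-gene mapping is exercised); methylation at probe level with a
probe annotation table carrying CpG-region and gene-region categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import OmicsMatrix, validate_annotation

# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Effect units: ``cnv_effect`` is log2-expression change per unit of CNV
    log-ratio (> 0); ``met_effect`` is log2-expression change per unit of
    beta (< 0). ``noise_sd`` is the residual SD of log2 expression.
    ``burden_coupling`` is the latent correlation between each sample's CNV
    and MET abnormality burdens.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_subtypes: int = 4
    subtype_proportions: tuple | None = None
    n_cnvcor_genes: int = 100
    n_metcor_genes: int = 100
    n_overlap_genes: int = 30
    cnv_effect: float = 1.0
    met_effect: float = -2.0
    noise_sd: float = 0.5
    burden_coupling: float = 0.6
    hazard_ratios: tuple | None = None
    censoring_rate: float = 0.3
    mutation_rates: dict | None = None
    seed: int = 0

    # genome / assay layout
    n_chromosomes: int = 4
    gene_length: int = 999
    gene_spacing: int = 10_000
    background_block_size: int = 8
    sex_probe_fraction: float = 0.02
    met_missing_fraction: float = 0.02
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.0
    nb_dispersion: float = 0.1
    # subtype signal scales (between-subtype SD vs within-subtype SD)
    cnv_subtype_sd: float = 0.4
    cnv_within_sd: float = 0.3
    cnv_background_sd: float = 0.10
    met_subtype_sd: float = 0.22
    met_within_sd: float = 0.10
    met_background_sd: float = 0.08
    # per-sample abnormality burden fraction = base + range * Phi(latent)
    burden_base: float = 0.05
    burden_range: float = 0.25

    def __post_init__(self) -> None:
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple([1.0 / self.n_subtypes] * self.n_subtypes)
        if self.hazard_ratios is None:
            base = (1.0, 1.6, 3.0, 2.2, 1.3, 2.6)
            self.hazard_ratios = tuple(base[i % len(base)] for i in range(self.n_subtypes))
        self.validate()
        if self.mutation_rates is None:
            # three mutation genes with subtype-skewed frequencies, placed on
            # the last gene ids so they never collide with planted sets
            names = [gene_name(self.n_genes - 1 - i, self.n_genes) for i in range(3)]
            profiles = [(0.05, 0.25, 0.65, 0.30), (0.55, 0.15, 0.10, 0.40),
                        (0.10, 0.12, 0.18, 0.10)]
            self.mutation_rates = {
                name: tuple(p[i % 4] for i in range(self.n_subtypes))
                for name, p in zip(names, profiles)
            }

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_subtypes", "n_cnvcor_genes",
                     "n_metcor_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_overlap_genes < 0:
            raise ValueError("n_overlap_genes must be >= 0")
        if len(self.subtype_proportions) != self.n_subtypes:
            raise ValueError("subtype_proportions length must equal n_subtypes")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-6:
            raise ValueError("subtype_proportions must sum to 1")
        if self.n_overlap_genes > min(self.n_cnvcor_genes, self.n_metcor_genes):
            raise ValueError("n_overlap_genes exceeds a planted set size")
        if self.n_cnvcor_genes + self.n_metcor_genes - self.n_overlap_genes > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.cnv_effect <= 0:
            raise ValueError("cnv_effect must be > 0")
        if self.met_effect >= 0:
            raise ValueError("met_effect must be < 0")
        if not 0 < self.burden_coupling < 1:
            raise ValueError("burden_coupling must be in (0, 1)")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        if len(self.hazard_ratios) != self.n_subtypes:
            raise ValueError("one hazard ratio per subtype required")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("hazard ratios must be > 0")


def gene_name(i: int, n_genes: int) -> str:
    width = max(4, len(str(n_genes - 1)))
    return f"G{i:0{width}d}"


def sample_name(i: int, n_samples: int) -> str:
    width = max(4, len(str(n_samples - 1)))
    return f"SAMP{i:0{width}d}"


# ---------------------------------------------------------------------------
# genome layout and probe annotation


def make_gene_model(config: SimConfig) -> pd.DataFrame:
    """Lay genes out on a toy genome of ``n_chromosomes`` acrocentric-free
    chromosomes with p/q arms; 1-based inclusive coordinates."""
    n = config.n_genes
    per_chrom = int(math.ceil(n / config.n_chromosomes))
    rows = []
    for i in range(n):
        chrom_idx, local = divmod(i, per_chrom)
        chrom = str(chrom_idx + 1)
        n_on_chrom = min(per_chrom, n - chrom_idx * per_chrom)
        arm = f"{chrom}p" if local < n_on_chrom / 2 else f"{chrom}q"
        start = local * config.gene_spacing + 1
        end = start + config.gene_length
        strand = "-" if i % 10 == 9 else "+"
        tss = start if strand == "+" else end
        rows.append((gene_name(i, n), chrom, arm, start, end, tss, strand))
    return pd.DataFrame(
        rows, columns=["gene", "chromosome", "arm", "start", "end", "tss", "strand"]
    )


def generate_probe_annotation(
    config: SimConfig,
    gene_model: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a probe annotation table for the toy genome.

    Every gene receives one promoter probe (CpG island, within 2500 bases
    upstream of the TSS); a deterministic subset of genes receives extra
    probes in other region categories. A configurable fraction of probes is
    placed on chromosome X with no gene assignment, to exercise
    sex-chromosome filtering. Each probe maps to exactly one gene or to none.
    """
    if gene_model is None:
        gene_model = make_gene_model(config)
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    rows = []
    probe_i = 0

    def add(chrom, arm, pos, gene, cpg, region, strand):
        nonlocal probe_i
        rows.append((f"cg{probe_i:07d}", chrom, arm, int(pos), gene, cpg, region, strand))
        probe_i += 1

    for i, g in enumerate(gene_model.itertuples(index=False)):
        offset = int(rng.integers(1, 2500))  # upstream distance from TSS
        if g.strand == "+":
            pos = max(1, g.tss - offset)
        else:
            pos = g.tss + offset
        add(g.chromosome, g.arm, pos, g.gene, "Island", "Promoter", g.strand)
        if i % 3 == 0:
            add(g.chromosome, g.arm, g.start + int(rng.integers(200, 800)),
                g.gene, "OpenSea", "Body", g.strand)
        if i % 5 == 0:
            add(g.chromosome, g.arm, g.start + int(rng.integers(0, 150)),
                g.gene, "Shore", "5'UTR", g.strand)
        if i % 7 == 0:
            add(g.chromosome, g.arm, g.start + int(rng.integers(100, 400)),
                g.gene, "Shelf", "FirstExon", g.strand)
    n_sex = int(round(config.sex_probe_fraction * probe_i))
    for _ in range(n_sex):
        add("X", "Xq", int(rng.integers(1, 10_000_000)), "", "OpenSea", "Intergenic", "+")
    ann = pd.DataFrame(rows, columns=[
        "probe_id", "chromosome", "arm", "position", "gene",
        "cpg_region", "gene_region", "strand"])
    return validate_annotation(ann)


# ---------------------------------------------------------------------------
# survival


def generate_survival(
    labels: pd.Series,
    hazard_ratios,
    censoring_rate: float,
    seed: int,
    baseline_hazard: float = 0.02,
) -> pd.DataFrame:
    """Exponential event times with subtype-specific hazards and independent
    exponential censoring whose rate is solved numerically so the expected
    censored fraction equals ``censoring_rate``.
    """
    if not 0 <= censoring_rate <= 1:
        raise ValueError("censoring_rate must be in [0, 1]")
    levels = sorted(pd.unique(labels))
    if len(hazard_ratios) != len(levels):
        raise ValueError("one hazard ratio per subtype level required")
    if any(h <= 0 for h in hazard_ratios):
        raise ValueError("hazard ratios must be > 0")
    rng = np.random.default_rng(seed)
    hr = dict(zip(levels, hazard_ratios))
    rates = np.array([baseline_hazard * hr[l] for l in labels])
    event_t = rng.exponential(1.0 / rates)
    if censoring_rate == 0:
        time, event = event_t, np.ones(len(labels), dtype=int)
    elif censoring_rate == 1:
        time, event = rng.exponential(1.0 / rates), np.zeros(len(labels), dtype=int)
    else:
        def censored_frac(lam_c):
            return float(np.mean(lam_c / (lam_c + rates))) - censoring_rate

        lam = optimize.brentq(censored_frac, 1e-12, 1e9)
        cens_t = rng.exponential(1.0 / lam, size=len(labels))
        event = (event_t <= cens_t).astype(int)
        time = np.minimum(event_t, cens_t)
    return pd.DataFrame({
        "sample": labels.index, "os_time": time, "os_event": event,
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortTruth:
    labels: pd.Series
    cnvcor_genes: list
    metcor_genes: list
    overlap_genes: list
    normal_means: dict
    burden_latent: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


@dataclass
class SyntheticCohort:
    cnv: OmicsMatrix
    segments: pd.DataFrame
    met: OmicsMatrix
    expr_counts: OmicsMatrix
    expr_log: OmicsMatrix
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    annotation: pd.DataFrame
    gene_model: pd.DataFrame
    truth: CohortTruth

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr_log.sample_ids


def _background_blocks(gene_model: pd.DataFrame, planted: set, block_size: int):
    """Group non-planted genes into runs of consecutive genes on the same arm
    (segment-level noise); planted genes become singleton blocks."""
    blocks = []
    current: list[int] = []
    current_arm = None
    for i, g in enumerate(gene_model.itertuples(index=False)):
        if g.gene in planted:
            if current:
                blocks.append(current)
                current = []
            blocks.append([i])
            current_arm = g.arm
            continue
        if current and (g.arm != current_arm or len(current) >= block_size):
            blocks.append(current)
            current = []
        current.append(i)
        current_arm = g.arm
    if current:
        blocks.append(current)
    return blocks


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical config and seed give
    bit-identical output."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (ss_labels, ss_plant, ss_cnv, ss_met, ss_expr, ss_burden, ss_surv,
     ss_mut, ss_ann, ss_miss) = (np.random.default_rng(c) for c in ss.spawn(10))

    n, p = config.n_samples, config.n_genes
    genes = [gene_name(i, p) for i in range(p)]
    samples = [sample_name(i, n) for i in range(n)]
    gene_model = make_gene_model(config)
    annotation = generate_probe_annotation(
        config, gene_model, seed=ss_ann.integers(2**31))

    # subtype labels
    labels_int = ss_labels.choice(
        config.n_subtypes, size=n, p=np.asarray(config.subtype_proportions))
    labels = pd.Series(
        [f"S{k + 1}" for k in labels_int], index=pd.Index(samples, name="sample"),
        name="subtype")

    # planted gene sets (random positions across the toy genome)
    perm = ss_plant.permutation(p)
    n_uniq = config.n_cnvcor_genes + config.n_metcor_genes - config.n_overlap_genes
    planted_idx = perm[:n_uniq]
    cnv_idx = np.sort(planted_idx[:config.n_cnvcor_genes])
    met_idx = np.sort(planted_idx[config.n_cnvcor_genes - config.n_overlap_genes:])
    cnvcor = [genes[i] for i in cnv_idx]
    metcor = [genes[i] for i in met_idx]
    overlap = sorted(set(cnvcor) & set(metcor))

    # per-sample abnormality-burden latents (Gaussian copula, corr = coupling)
    rho = config.burden_coupling
    z = ss_burden.standard_normal((n, 2))
    u_cnv = z[:, 0]
    u_met = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
    frac_cnv = config.burden_base + config.burden_range * stats.norm.cdf(u_cnv)
    frac_met = config.burden_base + config.burden_range * stats.norm.cdf(u_met)

    # ---- CNV: segment-level values over the toy genome -------------------
    blocks = _background_blocks(gene_model, set(cnvcor), config.background_block_size)
    n_blocks = len(blocks)
    block_sizes = np.array([len(b) for b in blocks])
    block_is_planted = np.array([len(b) == 1 and genes[b[0]] in set(cnvcor)
                                 for b in blocks])
    mu_cnv = ss_cnv.normal(0.0, config.cnv_subtype_sd,
                           (config.n_cnvcor_genes, config.n_subtypes))
    cnv_gene_row = {g: j for j, g in enumerate(cnvcor)}

    block_vals = np.empty((n_blocks, n))
    bg = ~block_is_planted
    block_vals[bg] = ss_cnv.normal(0.0, config.cnv_background_sd, (bg.sum(), n))
    for b in np.flatnonzero(block_is_planted):
        j = cnv_gene_row[genes[blocks[b][0]]]
        block_vals[b] = mu_cnv[j, labels_int] + ss_cnv.normal(
            0.0, config.cnv_within_sd, n)
    # burden overlay: per sample, push whole blocks to gain/loss until the
    # targeted fraction of genes is abnormal
    for s in range(n):
        target = int(round(frac_cnv[s] * p))
        order = ss_cnv.permutation(n_blocks)
        got = 0
        for b in order:
            if got >= target:
                break
            shift = ss_cnv.uniform(0.5, 0.9) * (1 if ss_cnv.random() < 0.5 else -1)
            block_vals[b, s] += shift
            got += block_sizes[b]

    cnv_values = np.empty((p, n))
    seg_rows = []
    for b, members in enumerate(blocks):
        cnv_values[members] = block_vals[b]
    cnv_df = pd.DataFrame(cnv_values, index=pd.Index(genes, name="gene"),
                          columns=samples)
    # segments mirror the block structure exactly
    for b, members in enumerate(blocks):
        chrom = gene_model.iloc[members[0]]["chromosome"]
        start = int(gene_model.iloc[members[0]]["start"])
        end = int(gene_model.iloc[members[-1]]["end"])
        for s in range(n):
            seg_rows.append((samples[s], chrom, start, end, len(members),
                             block_vals[b, s]))
    segments = pd.DataFrame(seg_rows, columns=[
        "sample", "chromosome", "start", "end", "num_mark", "seg_mean"])
    segments = segments.sort_values(["sample", "chromosome", "start"],
                                    kind="stable").reset_index(drop=True)

    # ---- MET: gene-level beta, then probe matrix -------------------------
    beta_base = ss_met.uniform(0.25, 0.75, p)
    met_rows = {g: j for j, g in enumerate(metcor)}
    mu_met = ss_met.normal(0.0, config.met_subtype_sd,
                           (config.n_metcor_genes, config.n_subtypes))
    beta = beta_base[:, None] + ss_met.normal(0.0, config.met_background_sd, (p, n))
    for g, j in met_rows.items():
        gi = genes.index(g)
        beta_base[gi] = ss_met.uniform(0.35, 0.65)
        beta[gi] = (beta_base[gi] + mu_met[j, labels_int]
                    + ss_met.normal(0.0, config.met_within_sd, n))
    # burden overlay: per sample, force a coupled fraction of genes to
    # hyper- (beta > 0.8) or hypo- (beta < 0.2) methylated extremes
    for s in range(n):
        k = int(round(frac_met[s] * p))
        chosen = ss_met.choice(p, size=k, replace=False)
        half = k // 2
        beta[chosen[:half], s] = ss_met.uniform(0.85, 0.98, half)
        beta[chosen[half:], s] = ss_met.uniform(0.02, 0.15, k - half)
    beta = np.clip(beta, 0.01, 0.99)

    # probe matrix: promoter probes carry the gene-level signal; extra
    # probes get independent noise around the gene baseline
    ann_idx = annotation.set_index("probe_id")
    probe_vals = np.empty((len(annotation), n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for r, probe in enumerate(annotation.itertuples(index=False)):
        if probe.gene == "":
            probe_vals[r] = np.clip(ss_met.uniform(0.05, 0.95)
                                    + ss_met.normal(0.0, 0.05, n), 0.01, 0.99)
        elif probe.gene_region == "Promoter":
            probe_vals[r] = beta[gene_pos[probe.gene]]
        else:
            probe_vals[r] = np.clip(beta_base[gene_pos[probe.gene]]
                                    + ss_met.normal(0.0, 0.08, n), 0.01, 0.99)
    met_df = pd.DataFrame(probe_vals, index=pd.Index(annotation["probe_id"],
                                                     name="probe_id"),
                          columns=samples)
    # inject missingness (never on promoter probes' high-missing subset)
    if config.met_missing_fraction > 0:
        mask = ss_miss.random(met_df.shape) < config.met_missing_fraction
        non_promoter = (ann_idx["gene_region"] != "Promoter").to_numpy()
        bad = ss_miss.choice(np.flatnonzero(non_promoter),
                             size=max(1, int(0.01 * len(annotation))), replace=False)
        mask[bad] = ss_miss.random((len(bad), n)) < 0.4
        met_df = met_df.mask(mask)

    # ---- expression ------------------------------------------------------
    baseline = ss_expr.normal(config.expr_baseline_mean, config.expr_baseline_sd, p)
    expr = baseline[:, None] + ss_expr.normal(0.0, config.noise_sd, (p, n))
    for g in cnvcor:
        gi = gene_pos[g]
        expr[gi] += config.cnv_effect * cnv_values[gi]
    for g in metcor:
        gi = gene_pos[g]
        expr[gi] += config.met_effect * (beta[gi] - beta_base[gi])
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)

    size_factors = np.exp(ss_expr.normal(0.0, 0.2, n))
    mu = size_factors[None, :] * np.exp2(expr)
    r_nb = 1.0 / config.nb_dispersion
    counts = ss_expr.negative_binomial(r_nb, r_nb / (r_nb + mu))
    counts_df = pd.DataFrame(counts.astype(np.int64),
                             index=pd.Index(genes, name="gene"), columns=samples)

    # ---- survival and mutations -----------------------------------------
    clinical = generate_survival(labels, config.hazard_ratios,
                                 config.censoring_rate,
                                 seed=int(ss_surv.integers(2**31)))
    maf_rows = []
    for g, rates in config.mutation_rates.items():
        rates = np.asarray(rates)
        mutated = ss_mut.random(n) < rates[labels_int]
        for s in np.flatnonzero(mutated):
            cls = "Missense_Mutation" if ss_mut.random() < 0.8 else "Nonsense_Mutation"
            maf_rows.append((g, samples[s], cls))
        silent = ss_mut.random(n) < 0.05
        for s in np.flatnonzero(silent):
            maf_rows.append((g, samples[s], "Silent"))
    mutations = pd.DataFrame(maf_rows, columns=[
        "Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"])
    mutations = mutations.sort_values(
        ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"],
        kind="stable").reset_index(drop=True)

    truth = CohortTruth(
        labels=labels,
        cnvcor_genes=cnvcor,
        metcor_genes=metcor,
        overlap_genes=overlap,
        normal_means={
            "EXPR": pd.Series(np.exp2(baseline), index=genes, name="normal_mean"),
            "MET": pd.Series(beta_base, index=genes, name="normal_beta"),
            "CNV": pd.Series(0.0, index=genes, name="normal_logratio"),
        },
        burden_latent=pd.DataFrame({
            "sample": samples, "frac_cnv": frac_cnv, "frac_met": frac_met}),
        config=config,
    )
    return SyntheticCohort(
        cnv=OmicsMatrix(cnv_df, "CNV"),
        segments=segments,
        met=OmicsMatrix(met_df, "MET"),
        expr_counts=OmicsMatrix(counts_df, "EXPR"),
        expr_log=OmicsMatrix(expr_df, "EXPR"),
        mutations=mutations,
        clinical=clinical,
        annotation=annotation,
        gene_model=gene_model,
        truth=truth,
    )
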