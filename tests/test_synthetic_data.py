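import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from regburden import enhancer_atlas as atlas
from regburden.intervals import GenomicInterval
from regburden.io_formats import write_fasta
from regburden.synthetic_data import (
    DnmSampler,
    ENHANCER_STATES,
    QUIESCENT_STATE,
    SyntheticConfig,
    generate_dnms,
    generate_genome,
    generate_regulatory_context,
    generate_segmentations,
    simulate_study,
    write_study,
)
from regburden.target_assignment import spearman_rho

from conftest import make_uniform_table


def tiny_config(**kw):
    defaults = dict(
        seed=3,
        chrom_lengths={"chr1": 400_000},
        genes_per_chrom=5,
        n_planted_specific=4,
        n_planted_shared=6,
        n_noise_enhancers=8,
        n_probands_case=4,
        n_probands_control=4,
        mean_dnms_per_proband=20,
        mean_dnms_control=20,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


# -- config and genome -------------------------------------------------------

def test_config_rejects_unaligned_chrom():
    with pytest.raises(ValueError, match="not divisible"):
        SyntheticConfig(chrom_lengths={"chr1": 1001})


def test_config_rejects_zero_length():
    with pytest.raises(ValueError, match="zero-length"):
        SyntheticConfig(chrom_lengths={"chr1": 0})


def test_config_rejects_beta_below_one():
    with pytest.raises(ValueError, match="burden multiplier"):
        SyntheticConfig(burden_multiplier=0.5)


def test_genome_alphabet_and_length():
    cfg = SyntheticConfig(seed=1, chrom_lengths={"chr1": 400})
    g = generate_genome(cfg)
    assert len(g["chr1"]) == 400
    assert set(g["chr1"]) <= set("ACGT")


def test_genome_determinism(tmp_path):
    cfg = SyntheticConfig(seed=1, chrom_lengths={"chr1": 2000})
    g1 = generate_genome(cfg)
    g2 = generate_genome(cfg)
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    write_fasta(p1, g1)
    write_fasta(p2, g2)
    assert p1.read_bytes() == p2.read_bytes()


def test_genome_seed_sensitivity():
    g1 = generate_genome(SyntheticConfig(seed=1, chrom_lengths={"chr1": 2000}))
    g2 = generate_genome(SyntheticConfig(seed=2, chrom_lengths={"chr1": 2000}))
    assert g1["chr1"] != g2["chr1"]


# -- segmentations -----------------------------------------------------------

def test_planted_specific_construction():
    cfg = tiny_config(n_planted_specific=5, genes_per_chrom=6)
    genome = generate_genome(cfg)
    seg = generate_segmentations(genome, cfg)
    gt = seg.ground_truth
    assert len(gt.specific) == 5
    w = cfg.window_bp
    fetal = set(cfg.fetal_tissues)
    for pe in gt.specific:
        iv = pe.interval
        for tissue in cfg.tissues:
            states = seg.tracks[tissue][iv.chrom][iv.start // w : iv.end // w]
            if tissue in fetal:
                assert all(s in ENHANCER_STATES for s in states)
            else:
                assert all(s == QUIESCENT_STATE for s in states)


def test_shared_enhancers_cover_most_tissues():
    cfg = tiny_config()
    genome = generate_genome(cfg)
    seg = generate_segmentations(genome, cfg)
    w = cfg.window_bp
    for iv in seg.ground_truth.shared:
        n_active = sum(
            1
            for t in cfg.tissues
            if all(
                s in ENHANCER_STATES
                for s in seg.tracks[t][iv.chrom][iv.start // w : iv.end // w]
            )
        )
        assert n_active >= 0.8 * cfg.n_tissues


def test_single_tissue_refused():
    cfg = tiny_config(n_tissues=1, n_fetal=1)
    genome = generate_genome(cfg)
    with pytest.raises(ValueError, match="single tissue"):
        generate_segmentations(genome, cfg)


def test_planted_count_exceeds_capacity():
    cfg = tiny_config(
        chrom_lengths={"chr1": 10_000}, genes_per_chrom=2,
        n_planted_specific=2, n_planted_shared=500,
    )
    genome = generate_genome(cfg)
    with pytest.raises(ValueError):
        generate_segmentations(genome, cfg)


def test_atlas_recovers_planted(small_study):
    seg = small_study.segmentations
    cfg = small_study.config
    recovered = atlas.build_atlas(
        seg.tracks, cfg.fetal_tissues, seg.peaks, seg.window_bp, fraction=0.35
    )
    planted = {pe.interval.id for pe in seg.ground_truth.specific}
    got = {e.id for e in recovered}
    assert len(planted & got) >= 0.8 * len(planted)


# -- DNMs --------------------------------------------------------------------

@pytest.fixture(scope="module")
def dnm_setup():
    cfg = tiny_config()
    genome = generate_genome(cfg)
    table = make_uniform_table()
    burden = [GenomicInterval("chr1", 50_000, 60_000), GenomicInterval("chr1", 200_000, 210_000)]
    return cfg, genome, table, burden


def test_dnms_zero_probands(dnm_setup):
    cfg, genome, table, burden = dnm_setup
    rng = np.random.default_rng(0)
    assert generate_dnms(genome, table, burden, 1.0, 0, 60, rng) == []


def test_dnms_burden_share_null(dnm_setup):
    cfg, genome, table, burden = dnm_setup
    sampler = DnmSampler(genome, table, burden, beta=1.0)
    rng = np.random.default_rng(1)
    recs = sampler.sample(1, 10_000, rng)
    n = len(recs)
    share = sampler.burden_share
    hits = sum(1 for r in recs if any(iv.contains_point(r.chrom, r.pos0) for iv in burden))
    se = np.sqrt(share * (1 - share) * n)
    assert abs(hits - share * n) < 3 * se


def test_dnms_beta_renormalization(dnm_setup):
    cfg, genome, table, burden = dnm_setup
    beta = 3.0
    sampler = DnmSampler(genome, table, burden, beta=beta)
    # analytic share under beta
    base = DnmSampler(genome, table, burden, beta=1.0)
    w_b = base.burden_baseline
    w_all = base.baseline_total
    expected_share = beta * w_b / (beta * w_b + (w_all - w_b))
    assert sampler.burden_share == pytest.approx(expected_share)
    rng = np.random.default_rng(2)
    recs = sampler.sample(1, 20_000, rng)
    hits = sum(1 for r in recs if any(iv.contains_point(r.chrom, r.pos0) for iv in burden))
    n = len(recs)
    se = np.sqrt(expected_share * (1 - expected_share) * n)
    assert abs(hits - expected_share * n) < 3 * se


def test_dnms_ref_matches_genome(dnm_setup):
    cfg, genome, table, burden = dnm_setup
    rng = np.random.default_rng(3)
    recs = generate_dnms(genome, table, None, 1.0, 3, 50, rng)
    for r in recs:
        assert genome[r.chrom][r.pos0] == r.ref
        assert r.ref != r.alt


def test_dnms_burden_outside_genome_errors(dnm_setup):
    cfg, genome, table, _ = dnm_setup
    bad = [GenomicInterval("chr9", 0, 100)]
    with pytest.raises(ValueError, match="outside genome"):
        DnmSampler(genome, table, bad)


def test_dnm_context_frequencies_chi_square():
    """Empirical per-context DNM density converges to the rate table."""
    cfg = SyntheticConfig(seed=9, chrom_lengths={"chr1": 100_000}, genes_per_chrom=2,
                          n_planted_specific=1, n_planted_shared=1, n_noise_enhancers=0)
    genome = generate_genome(cfg)
    from regburden.mutability import MutabilityTable, context_codes

    table = MutabilityTable.default()
    sampler = DnmSampler(genome, table)
    rng = np.random.default_rng(12)
    recs = sampler.sample(1, 100_000, rng)
    codes = context_codes(genome["chr1"])
    # expected share per context index from the weight vector
    weights = np.zeros(64)
    for idx in range(64):
        weights[idx] = table.context_total[idx] * np.sum(codes == idx)
    weights /= weights.sum()
    observed = np.zeros(64)
    pos = np.array([r.pos0 for r in recs])
    ctx = codes[pos]
    for idx in range(64):
        observed[idx] = np.sum(ctx == idx)
    keep = weights * len(recs) >= 5
    chi = stats.chisquare(observed[keep], weights[keep] / weights[keep].sum() * observed[keep].sum())
    assert chi.pvalue > 0.01


# -- regulatory context ------------------------------------------------------

def test_pchic_link_yields_one_bedpe_row(small_study):
    ctx = small_study.context
    gt = small_study.segmentations.ground_truth
    n_pchic = sum(1 for _, _, tier in gt.links if tier == "pchic")
    assert len(ctx.interactions) == n_pchic
    # each interaction joins the enhancer's fragment with the promoter's
    for enh_id, gene, tier in gt.links:
        if tier != "pchic":
            continue
        pe = next(p for p in gt.specific if p.interval.id == enh_id)
        row = ctx.genes[ctx.genes.gene == gene].iloc[0]
        hit = [
            x
            for x in ctx.interactions
            if (x.fragA.overlaps(pe.interval) or x.fragB.overlaps(pe.interval))
        ]
        assert len(hit) == 1
        other = hit[0].fragB if hit[0].fragA.overlaps(pe.interval) else hit[0].fragA
        assert other.start <= row.tss < other.end


def test_correlation_link_high_rho(small_study):
    ctx = small_study.context
    gt = small_study.segmentations.ground_truth
    checked = 0
    for enh_id, gene, tier in gt.links:
        if tier == "h3k27ac_corr":
            rho = spearman_rho(ctx.enh_h3k27ac.loc[enh_id], ctx.prom_h3k27ac.loc[gene])
        elif tier == "chromhmm_corr":
            rho = spearman_rho(ctx.enh_chromhmm.loc[enh_id], ctx.prom_chromhmm.loc[gene])
        else:
            continue
        checked += 1
        assert rho > 0.8
    assert checked >= 2


def test_no_links_no_interactions():
    cfg = tiny_config(n_planted_specific=0)
    genome = generate_genome(cfg)
    seg = generate_segmentations(genome, cfg)
    ctx = generate_regulatory_context(cfg, seg.ground_truth)
    assert ctx.interactions == []


def test_links_respect_tads(small_study):
    from regburden.target_assignment import tad_of

    ctx = small_study.context
    gt = small_study.segmentations.ground_truth
    for pe in gt.specific:
        tad = tad_of(pe.interval, ctx.tads)
        assert tad is not None
        row = ctx.genes[ctx.genes.gene == pe.gene].iloc[0]
        assert tad.contains_point(row.chrom, row.tss)


def test_target_genes_expressed(small_study):
    ctx = small_study.context
    targets = {g for _, g, _ in small_study.segmentations.ground_truth.links}
    expr = dict(zip(ctx.genes.gene, ctx.genes.tpm))
    assert all(expr[g] >= 1 for g in targets)


# -- whole-study determinism -------------------------------------------------

def _dir_hash(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def test_write_study_byte_identical(tmp_path):
    cfg = tiny_config()
    s1 = simulate_study(cfg)
    s2 = simulate_study(cfg)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_study(s1, d1)
    write_study(s2, d2)
    assert _dir_hash(d1) == _dir_hash(d2)
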