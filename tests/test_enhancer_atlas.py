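import numpy as np
import pandas as pd
import pytest

from regburden.enhancer_atlas import (
    EnhancerRecord,
    build_atlas,
    intersect_open_chromatin,
    load_segmentation,
    merge_enhancer_windows,
    merge_tissue_sets,
    score_across_tissues,
    select_top_fraction,
    specificity_zscores,
    tissue_specific_genes,
)
from regburden.intervals import GenomicInterval

W = 200
E, Q, P = "7_Enh", "15_Quies", "1_TssA"


def track(states: list[str]) -> dict[str, np.ndarray]:
    return {"chr1": np.array(states, dtype="<U16")}


# -- merge_enhancer_windows ---------------------------------------------------

def test_merge_consecutive_run():
    recs = merge_enhancer_windows(track([E, E, E]), W, "t0")
    assert len(recs) == 1
    assert (recs[0].start, recs[0].end, recs[0].score) == (0, 600, 3)


def test_merge_split_by_quiescent():
    recs = merge_enhancer_windows(track([E, Q, E]), W, "t0")
    assert [(r.start, r.end, r.score) for r in recs] == [(0, 200, 1), (400, 600, 1)]


def test_merge_mixed_enhancer_states_coalesce():
    recs = merge_enhancer_windows(track(["6_EnhG", E, "6_EnhG"]), W, "t0")
    assert len(recs) == 1 and recs[0].score == 3


def test_merge_no_enhancers():
    assert merge_enhancer_windows(track([Q, P, Q]), W, "t0") == []


def test_load_segmentation_rejects_overlap(tmp_path):
    p = tmp_path / "seg.bed"
    p.write_text("chr1\t0\t400\t7_Enh\nchr1\t200\t600\t15_Quies\n")
    with pytest.raises(ValueError, match="overlapping"):
        load_segmentation(str(p), W)


def test_load_segmentation_rejects_unaligned(tmp_path):
    p = tmp_path / "seg.bed"
    p.write_text("chr1\t0\t150\t7_Enh\n")
    with pytest.raises(ValueError, match="not aligned"):
        load_segmentation(str(p), W)


def test_load_segmentation_round_trip(tmp_path):
    p = tmp_path / "seg.bed"
    p.write_text("chr1\t0\t400\t7_Enh\nchr1\t400\t600\t15_Quies\n")
    t = load_segmentation(str(p), W)
    assert list(t["chr1"]) == [E, E, Q]


# -- score_across_tissues -----------------------------------------------------

def make_tracks(per_tissue: dict[str, list[str]]):
    return {tissue: track(states) for tissue, states in per_tissue.items()}


def test_scores_shared_enhancer():
    tracks = make_tracks({"a": [E, E], "b": [E, E], "c": [E, E]})
    recs = merge_enhancer_windows(tracks["a"], W, "a")
    score_across_tissues(recs, tracks, W, ["a", "b", "c"])
    assert list(recs[0].tissue_scores) == [2, 2, 2]


def test_scores_specific_enhancer():
    tracks = make_tracks({"a": [E, E], "b": [Q, Q], "c": [Q, Q]})
    recs = merge_enhancer_windows(tracks["a"], W, "a")
    score_across_tissues(recs, tracks, W, ["a", "b", "c"])
    assert list(recs[0].tissue_scores) == [2, 0, 0]


def test_scores_brute_force_oracle(rng):
    tissues = [f"t{i}" for i in range(5)]
    n_win = 40
    tracks = {
        t: {"chr1": rng.choice([E, Q, P, "6_EnhG"], size=n_win).astype("<U16")}
        for t in tissues
    }
    recs = merge_enhancer_windows(tracks["t0"], W, "t0")
    score_across_tissues(recs, tracks, W, tissues)
    for r in recs:
        for ti, t in enumerate(tissues):
            brute = sum(
                1
                for wi in range(r.start // W, r.end // W)
                if tracks[t]["chr1"][wi] in ("7_Enh", "6_EnhG")
            )
            assert r.tissue_scores[ti] == brute


def test_scores_missing_window_errors():
    tracks = {"a": track([E, E]), "b": {"chr1": np.array([E], dtype="<U16")}}
    recs = merge_enhancer_windows(tracks["a"], W, "a")
    with pytest.raises(ValueError, match="missing windows"):
        score_across_tissues(recs, tracks, W, ["a", "b"])


# -- specificity z ------------------------------------------------------------

def rec(scores, source_idx=0, tissues=None):
    tissues = tissues or [f"t{i}" for i in range(len(scores))]
    r = EnhancerRecord("chr1", 0, W * scores[source_idx], scores[source_idx], tissues[source_idx])
    r.tissue_scores = np.array(scores)
    return r, tissues


def test_z_closed_form():
    r, tissues = rec([3, 0, 0, 0])
    specificity_zscores([r], tissues)
    scores = np.array([3, 0, 0, 0], dtype=float)
    expected = (3 - scores.mean()) / scores.std()
    assert r.z == pytest.approx(expected)


def test_z_zero_variance_flagged():
    r, tissues = rec([2, 2, 2, 2])
    specificity_zscores([r], tissues)
    assert r.z == 0.0 and not r.specific


def test_z_deterministic_for_identical_vectors():
    r1, tissues = rec([3, 1, 0, 0])
    r2, _ = rec([3, 1, 0, 0])
    specificity_zscores([r1, r2], tissues)
    assert r1.z == r2.z


def test_z_requires_two_tissues():
    r, _ = rec([3])
    with pytest.raises(ValueError):
        specificity_zscores([r], ["t0"])


def test_z_permutation_invariance():
    """Reordering non-source tissues leaves z unchanged."""
    r1, tissues = rec([3, 2, 0, 1])
    specificity_zscores([r1], tissues)
    r2 = EnhancerRecord("chr1", 0, 600, 3, "t0")
    r2.tissue_scores = np.array([3, 1, 2, 0])  # permuted others
    specificity_zscores([r2], ["t0", "t3", "t1", "t2"])
    assert r1.z == pytest.approx(r2.z)


# -- selection ----------------------------------------------------------------

def test_select_exact_fraction():
    records = []
    for i in range(100):
        r, _ = rec([i, 0, 0, 0])
        r.z = float(i)
        r.start, r.end = i * W, (i + 1) * W
        records.append(r)
    assert len(select_top_fraction(records, 0.35)) == 35


def test_select_identity_fraction():
    records = []
    for i in range(10):
        r, _ = rec([1, 0, 0, 0])
        r.z = float(i)
        records.append(r)
    selected = select_top_fraction(records, 1.0)
    assert {id(r) for r in selected} == {id(r) for r in records}


def test_select_empty():
    assert select_top_fraction([], 0.35) == []


def test_select_planted_specific_dominate():
    records = []
    for i in range(5):  # planted: high z
        r, _ = rec([4, 4, 0, 0, 0, 0, 0, 0, 0, 0])
        r.z = 2.0
        r.start, r.end = i * 1000, i * 1000 + 800
        records.append(r)
    for i in range(45):  # shared: low z
        r, _ = rec([4] * 9 + [0])
        r.z = 0.33
        r.start, r.end = 100_000 + i * 1000, 100_000 + i * 1000 + 800
        records.append(r)
    selected = select_top_fraction(records, 0.35)
    assert len(selected) == 18
    assert all(r.z == 2.0 for r in selected[:5])


# -- open chromatin intersection ----------------------------------------------

def test_intersect_one_bp_overlap_kept():
    r = EnhancerRecord("chr1", 100, 300, 1, "t0")
    assert intersect_open_chromatin([r], [GenomicInterval("chr1", 299, 400)]) == [r]


def test_intersect_abutting_dropped():
    r = EnhancerRecord("chr1", 100, 300, 1, "t0")
    assert intersect_open_chromatin([r], [GenomicInterval("chr1", 300, 400)]) == []


def test_intersect_empty_peaks():
    r = EnhancerRecord("chr1", 100, 300, 1, "t0")
    assert intersect_open_chromatin([r], []) == []


def test_intersect_brute_force_oracle(rng):
    enh = [
        EnhancerRecord("chr1", int(s), int(s) + int(l), 1, "t0")
        for s, l in zip(rng.integers(0, 5000, 40), rng.integers(1, 300, 40))
    ]
    peaks = [
        GenomicInterval("chr1", int(s), int(s) + int(l))
        for s, l in zip(rng.integers(0, 5000, 20), rng.integers(1, 200, 20))
    ]
    got = {id(e) for e in intersect_open_chromatin(enh, peaks)}
    brute = {
        id(e)
        for e in enh
        if any(e.start < p.end and p.start < e.end for p in peaks)
    }
    assert got == brute


# -- merge_tissue_sets --------------------------------------------------------

def _recs(spans):
    return [EnhancerRecord("chr1", s, e, (e - s) // W, "t") for s, e in spans]


def test_merge_sets_idempotent():
    a = _recs([(0, 400), (1000, 1400)])
    merged = merge_tissue_sets(a, a)
    assert [(m.start, m.end) for m in merged] == [(0, 400), (1000, 1400)]


def test_merge_sets_union():
    merged = merge_tissue_sets(_recs([(0, 400)]), _recs([(200, 600)]))
    assert [(m.start, m.end) for m in merged] == [(0, 600)]
    assert merged[0].z is None


def test_merge_sets_disjoint_sorted():
    merged = merge_tissue_sets(_recs([(1000, 1200)]), _recs([(0, 200)]))
    assert [(m.start, m.end) for m in merged] == [(0, 200), (1000, 1200)]


# -- tissue-specific genes ----------------------------------------------------

def test_specific_gene_selected():
    df = pd.DataFrame(
        [[50.0] + [1.0] * 56], index=["g1"], columns=[f"t{i}" for i in range(57)]
    )
    assert tissue_specific_genes(df, "t0") == ["g1"]


def test_constant_gene_not_selected():
    df = pd.DataFrame([[5.0] * 10], index=["g1"], columns=[f"t{i}" for i in range(10)])
    assert tissue_specific_genes(df, "t0") == []


def test_z_exactly_two_excluded():
    # [1,0,0,0,0]: mean 0.2, population sd 0.4 -> z exactly 2 for the focal value
    df = pd.DataFrame([[1.0, 0, 0, 0, 0]], index=["g1"], columns=list("abcde"))
    vals = df.iloc[0].to_numpy()
    assert (vals[0] - vals.mean()) / vals.std() == pytest.approx(2.0)
    assert tissue_specific_genes(df, "a") == []


def test_tissue_specific_genes_requires_two_tissues():
    df = pd.DataFrame([[5.0]], index=["g1"], columns=["a"])
    with pytest.raises(ValueError):
        tissue_specific_genes(df, "a")


# -- atlas invariants on synthetic data ---------------------------------------

def test_atlas_outputs_sorted_nonoverlapping(small_study):
    seg = small_study.segmentations
    cfg = small_study.config
    final = build_atlas(seg.tracks, cfg.fetal_tissues, seg.peaks, seg.window_bp)
    for a, b in zip(final, final[1:]):
        if a.chrom == b.chrom:
            assert a.end <= b.start
        assert 0 <= a.start < a.end


def test_atlas_source_score_is_max_when_specific(small_study):
    seg = small_study.segmentations
    cfg = small_study.config
    tissues = list(seg.tracks)
    from regburden.enhancer_atlas import (
        merge_enhancer_windows as mew,
        score_across_tissues as sat,
        specificity_zscores as sz,
    )

    t = cfg.fetal_tissues[0]
    enh = mew(seg.tracks[t], seg.window_bp, t)
    sat(enh, seg.tracks, seg.window_bp, tissues)
    sz(enh, tissues)
    planted = {pe.interval.id for pe in seg.ground_truth.specific}
    for e in enh:
        if e.id in planted and e.z and e.z > 0:
            src = tissues.index(t)
            assert e.tissue_scores[src] == e.tissue_scores.max()
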