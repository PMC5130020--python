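"""Control-referenced z-scoring, group averaging, UPGMA, cross-dataset
signature validation."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from amlmo import (
    ExpressionMatrix,
    SampleDesign,
    average_groups,
    upgma,
    upgma_from_distance,
    validate_signature,
    zscore_against_controls,
)
from amlmo.simulate import generate_validation_datasets

from conftest import build_dataset


def _case_control_base(z=2.0, noise_sd=0.5, n_genes=17, seed=1, groups=("RF12-p", "RF26-p", "MLP3-ivp")):
    """Base dataset where every case group shares one planted z-effect
    pattern of the given size."""
    rng = np.random.default_rng(seed)
    pattern = rng.choice([-1.0, 1.0], n_genes) * z * noise_sd
    gv = {"control": 8.0 + rng.normal(0, noise_sd, (n_genes, 4))}
    for g in groups:
        gv[g] = 8.0 + pattern[:, None] + rng.normal(0, noise_sd, (n_genes, 4))
    return build_dataset(gv, feature_ids=[f"G{i:03d}" for i in range(n_genes)], dataset_label="mouse")


class TestZScore:
    def test_control_profile_mean_zero_sd_one(self):
        m, d = _case_control_base()
        z = zscore_against_controls(m, d)
        ctrl = z.values[z.reference_samples]
        assert np.allclose(ctrl.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(ctrl.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_definition(self):
        gv = {"control": np.array([[6.0, 10.0]]), "RF12-p": np.array([[10.0]])}
        m, d = build_dataset(gv)
        z = zscore_against_controls(m, d)
        # control mean 8, sd (ddof=1) = 2*sqrt(2)/sqrt(2)... compute directly
        sd = np.std([6, 10], ddof=1)
        assert z.values.loc["f1", "RF12-p_1"] == pytest.approx((10 - 8) / sd)

    def test_zero_control_variance_feature_excluded(self):
        gv = {"control": np.array([[5.0, 5.0], [1.0, 2.0]]), "RF12-p": np.array([[7.0], [3.0]])}
        m, d = build_dataset(gv)
        z = zscore_against_controls(m, d)
        assert z.unscorable == ["f1"]
        assert list(z.values.index) == ["f2"]

    def test_affine_invariance(self):
        m, d = _case_control_base()
        z1 = zscore_against_controls(m, d)
        m2 = ExpressionMatrix(m.values * 3.7 - 12.0, dataset_label=m.dataset_label)
        z2 = zscore_against_controls(m2, d)
        pd.testing.assert_frame_equal(z1.values, z2.values, atol=1e-9, rtol=0)

    def test_requires_two_controls(self):
        gv = {"control": np.array([[5.0]]), "RF12-p": np.array([[7.0, 8.0]])}
        m, d = build_dataset(gv)
        with pytest.raises(ValueError, match="control"):
            zscore_against_controls(m, d)


class TestAverageGroups:
    def test_single_sample_group_unchanged_and_identical_replicates(self):
        gv = {"control": np.array([[2.0, 2.0]]), "RF12-p": np.array([[5.0]])}
        m, d = build_dataset(gv)
        out = average_groups(m.values, d, by_dataset=False)
        assert out.loc["f1", "control"] == 2.0
        assert out.loc["f1", "RF12-p"] == 5.0

    def test_matches_bruteforce_mean_with_missing(self):
        rng = np.random.default_rng(5)
        gv = {"control": rng.normal(size=(6, 4)), "MLP3-cl": rng.normal(size=(6, 4))}
        m, d = build_dataset(gv)
        vals = m.values.copy()
        vals.iloc[0, 0] = np.nan
        out = average_groups(vals, d, by_dataset=False)
        ctrl_cols = [c for c in vals.columns if c.startswith("control")]
        expect = np.nanmean(vals[ctrl_cols].to_numpy(), axis=1)
        assert np.allclose(out["control"].to_numpy(), expect)


def _bruteforce_cophenetic(dist: pd.DataFrame, tree):
    """Replay merges, checking each height equals the mean cross-cluster
    distance; return max abs deviation over all leaf pairs."""
    labels = tree.leaf_labels
    err = 0.0
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            h = tree.cophenetic(a, b)
            # find merge joining a and b; members of the two sides
            for node_offset, (l, r, hh) in enumerate(tree.merges):
                left = {labels[x] for x in tree.leaves_under(l)}
                right = {labels[x] for x in tree.leaves_under(r)}
                if (a in left and b in right) or (a in right and b in left):
                    avg = np.mean([dist.loc[x, y] for x in left for y in right])
                    err = max(err, abs(h - avg))
                    break
    return err


class TestUPGMA:
    def test_two_items_merge_at_their_distance(self):
        d = pd.DataFrame([[0, 3.2], [3.2, 0]], index=["A", "B"], columns=["A", "B"], dtype=float)
        t = upgma_from_distance(d)
        assert t.merges == [(0, 1, 3.2)]

    def test_three_point_hand_example(self):
        d = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        t = upgma_from_distance(d)
        heights = [h for *_, h in t.merges]
        assert heights == [2.0, 4.0]
        assert t.cophenetic("A", "C") == 4.0

    def test_matches_bruteforce_and_scipy_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(3, 9))
            pts = rng.normal(size=(n, 3))
            dm = squareform(pdist(pts))
            labels = [f"L{i}" for i in range(n)]
            dist = pd.DataFrame(dm, index=labels, columns=labels)
            t = upgma_from_distance(dist)
            assert _bruteforce_cophenetic(dist, t) < 1e-9
            # scipy average linkage as the independent oracle
            Z = hierarchy.linkage(squareform(dm), method="average")
            ours = sorted(h for *_, h in t.merges)
            assert np.allclose(ours, sorted(Z[:, 2]))

    def test_column_order_invariance(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"f{i}" for i in range(5)],
                            columns=list("FCEABD"))
        t1 = upgma(vals)
        t2 = upgma(vals[list("ABCDEF")])
        assert t1.leaf_labels == t2.leaf_labels
        for i, a in enumerate(t1.leaf_labels):
            for b in t1.leaf_labels[i + 1 :]:
                assert t1.cophenetic(a, b) == pytest.approx(t2.cophenetic(a, b))

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="2 items"):
            upgma(pd.DataFrame({"only": [1.0, 2.0]}))


class TestValidateSignature:
    def test_planted_case_control_structure_recovered(self):
        m, d = _case_control_base(z=2.0, seed=2)
        datasets, _ = generate_validation_datasets(m, d, n_datasets=2, noise_sd=0.5, seed=3)
        rep = validate_signature(list(m.feature_ids), [(m, d)] + datasets)
        assert rep.adjusted_rand == 1.0
        case = {g for g, v in rep.case_control.items() if v == 1}
        part_by_case = {rep.partition[g] for g in case}
        assert len(part_by_case) == 1  # all case groups on one side of the cut

    def test_no_signal_gives_near_zero_ari(self):
        rng = np.random.default_rng(4)
        gv = {g: rng.normal(8, 1, (17, 4)) for g in ("control", "RF12-p", "RF26-p", "MLP3-ivp")}
        m, d = build_dataset(gv, feature_ids=[f"G{i}" for i in range(17)])
        rep = validate_signature(list(m.feature_ids), [(m, d)])
        assert rep.adjusted_rand < 0.5

    def test_label_permutation_destroys_separation(self):
        m, d = _case_control_base(z=2.0, seed=5)
        datasets, _ = generate_validation_datasets(m, d, n_datasets=2, noise_sd=0.5, seed=6)
        all_sets = [(m, d)] + datasets
        rng = np.random.default_rng(9)
        low = 0
        trials = 20
        for _ in range(trials):
            permuted = []
            for mat, des in all_sets:
                t = des.table.copy()
                idx = rng.permutation(len(t))
                t[["material_class", "line"]] = t[["material_class", "line"]].to_numpy()[idx]
                try:
                    permuted.append((mat, SampleDesign(t)))
                except Exception:
                    permuted.append((mat, des))
            try:
                ari = validate_signature(list(m.feature_ids), permuted).adjusted_rand
            except ValueError:
                ari = 0.0
            low += ari <= 0.2
        assert low / trials >= 0.9

    def test_missing_genes_abort_below_half(self):
        m, d = _case_control_base(seed=7)
        small = ExpressionMatrix(m.values.iloc[:5], dataset_label="mouse")
        with pytest.raises(ValueError, match="signature genes"):
            validate_signature(list(m.feature_ids), [(small, d)])
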