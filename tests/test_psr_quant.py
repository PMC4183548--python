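"""Birefringence counting, replicate averaging, and reference normalization."""

import numpy as np
import pandas as pd
import pytest

from fibroquant.color_model import BIN_NAMES, hsb_to_rgb
from fibroquant.preprocess import ROISpec, UnquantifiableImageError, build_roi
from fibroquant.psr_quant import (
    BirefringenceResult,
    average_replicates,
    normalize_to_reference,
    quantify_birefringence,
    samples_to_frame,
)
from fibroquant.synthetic_data import PSRParams, gen_psr_pair


def full_roi(shape):
    return ROISpec(mode="provided", mask=np.ones(shape, dtype=bool), roi_size=shape[0] * shape[1])


def painted(shape, spots):
    """Black image with pixels painted at given HSB colours: [(slice, (h,s,b))]."""
    img = np.zeros((*shape, 3), dtype=np.uint8)
    for sl, hsb in spots:
        img[sl] = hsb_to_rgb(np.array(hsb))
    return img


class TestQuantifyBirefringence:
    def test_red_only_field(self):
        img = painted((10, 10), [((slice(0, 2), slice(None)), (5, 255, 255))])
        res = quantify_birefringence(img, full_roi((10, 10)))
        assert res.total_fraction == pytest.approx(0.20)
        assert res.counts["red"] == 20 and res.total_positive == 20
        assert res.proportions["red"] == 1.0

    def test_red_green_split(self):
        img = painted(
            (10, 10),
            [((0, slice(None)), (5, 255, 255)), ((1, slice(None)), (60, 255, 255))],
        )
        res = quantify_birefringence(img, full_roi((10, 10)))
        assert res.proportions["red"] == 0.5 and res.proportions["green"] == 0.5
        assert res.total_fraction == pytest.approx(0.2)

    def test_counts_restricted_to_roi(self):
        img = painted((10, 10), [((slice(None), slice(None)), (5, 255, 255))])
        mask = np.zeros((10, 10), dtype=bool)
        mask[:3] = True
        res = quantify_birefringence(img, ROISpec("provided", mask, 30))
        assert res.counts["red"] == 30 and res.roi_size == 30

    def test_empty_roi_unquantifiable(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        roi = ROISpec("provided", np.zeros((4, 4), dtype=bool), 0)
        with pytest.raises(UnquantifiableImageError):
            quantify_birefringence(img, roi)

    def test_invariants_hold(self):
        res = BirefringenceResult(
            counts={"red": 3, "orange": 2, "yellow": 0, "green": 5}, roi_size=50
        )
        assert res.total_positive == 10
        assert res.total_fraction == 0.2
        assert sum(res.proportions.values()) == pytest.approx(1.0)

    def test_zero_positive_proportions_undefined(self):
        res = BirefringenceResult(
            counts={b: 0 for b in BIN_NAMES}, roi_size=10
        )
        assert res.total_positive == 0 and res.proportions is None

    def test_permutation_invariance(self, rng):
        _, pol, gt = gen_psr_pair(PSRParams(seed=11, lumen_count=0))
        res = quantify_birefringence(pol, full_roi(pol.shape[:2]))
        flat = pol.reshape(-1, 3)
        perm = rng.permutation(flat.shape[0])
        shuffled = flat[perm].reshape(pol.shape)
        res2 = quantify_birefringence(shuffled, full_roi(pol.shape[:2]))
        assert res.counts == res2.counts

    def test_pixel_replication_scales_counts(self):
        _, pol, _ = gen_psr_pair(PSRParams(seed=12, lumen_count=0, shape=(48, 48)))
        res = quantify_birefringence(pol, full_roi(pol.shape[:2]))
        big = np.kron(pol, np.ones((2, 2, 1), dtype=np.uint8))
        res2 = quantify_birefringence(big, full_roi(big.shape[:2]))
        assert res2.counts == {b: 4 * c for b, c in res.counts.items()}
        assert res2.total_fraction == pytest.approx(res.total_fraction)
        for b in BIN_NAMES:
            if res.proportions is not None:
                assert res2.proportions[b] == pytest.approx(res.proportions[b])

    def test_exact_ground_truth_recovery(self, config):
        from fibroquant.io_cli import process_psr_pair

        bf, pol, gt = gen_psr_pair(PSRParams(seed=21))
        res = process_psr_pair(bf, pol, config)
        assert res.counts == gt.counts


class TestAverageReplicates:
    def test_mean_of_three_fractions(self):
        reps = [
            BirefringenceResult(counts={"red": int(f * 100), "orange": 0, "yellow": 0, "green": 0}, roi_size=100)
            for f in (0.4, 0.5, 0.6)
        ]
        assert average_replicates(reps).total_fraction == pytest.approx(0.5)

    def test_single_replicate_identity(self):
        rep = BirefringenceResult(
            counts={"red": 10, "orange": 0, "yellow": 0, "green": 30}, roi_size=100
        )
        s = average_replicates([rep], patient_id="p1")
        assert s.total_fraction == rep.total_fraction
        assert s.proportions == rep.proportions

    def test_two_bin_proportion_means(self):
        reps = [
            BirefringenceResult(counts={"red": 20, "orange": 0, "yellow": 0, "green": 80}, roi_size=100),
            BirefringenceResult(counts={"red": 40, "orange": 0, "yellow": 0, "green": 60}, roi_size=100),
        ]
        s = average_replicates(reps)
        assert s.proportions["red"] == pytest.approx(0.3)
        assert s.proportions["green"] == pytest.approx(0.7)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])

    def test_zero_positive_replicate_kept_for_fraction_only(self):
        blank = BirefringenceResult(counts={b: 0 for b in BIN_NAMES}, roi_size=100)
        red = BirefringenceResult(
            counts={"red": 50, "orange": 0, "yellow": 0, "green": 0}, roi_size=100
        )
        s = average_replicates([blank, red])
        assert s.total_fraction == pytest.approx(0.25)  # blank counts toward fraction
        assert s.proportions["red"] == 1.0  # but not toward proportions


class TestNormalizeToReference:
    def frame(self, props_by_group):
        rows = []
        for group, props in props_by_group:
            row = {"group": group, "total_fraction": 0.5}
            for b in BIN_NAMES:
                row[f"prop_{b}"] = props
            rows.append(row)
        return pd.DataFrame(rows)

    def test_two_sample_reference(self):
        df = self.frame([("ref", 0.2), ("ref", 0.4)])
        out = normalize_to_reference(df, "ref")
        assert out["norm_red"].tolist() == pytest.approx([2 / 3, 4 / 3])
        assert out["norm_red"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_single_sample_reference_is_exactly_one(self):
        df = self.frame([("ref", 0.37), ("other", 0.5)])
        out = normalize_to_reference(df, "ref")
        assert out.loc[out.group == "ref", "norm_green"].iloc[0] == 1.0

    def test_reference_mean_exactly_one_per_bin(self, rng):
        df = self.frame([("ref", p) for p in rng.uniform(0.1, 0.9, 40)] +
                        [("other", p) for p in rng.uniform(0.1, 0.9, 40)])
        out = normalize_to_reference(df, "ref")
        for b in BIN_NAMES:
            ref_mean = out.loc[out.group == "ref", f"norm_{b}"].mean()
            assert ref_mean == pytest.approx(1.0, abs=1e-9)

    def test_zero_reference_mean_names_bin(self):
        df = self.frame([("ref", 0.0), ("other", 0.5)])
        with pytest.raises(ValueError, match="prop_red"):
            normalize_to_reference(df, "ref")

    def test_missing_reference_group(self):
        df = self.frame([("a", 0.5)])
        with pytest.raises(ValueError, match="reference"):
            normalize_to_reference(df, "zzz")

    def test_identical_distributions_give_similar_group_means(self, rng):
        props = rng.uniform(0.2, 0.6, 400)
        df = self.frame(
            [("ref", p) for p in props[:200]] + [("other", p) for p in props[200:]]
        )
        out = normalize_to_reference(df, "ref")
        for b in BIN_NAMES:
            delta = abs(out.loc[out.group == "other", f"norm_{b}"].mean() - 1.0)
            assert delta < 0.05


def test_samples_to_frame_shape():
    rep = BirefringenceResult(
        counts={"red": 10, "orange": 5, "yellow": 0, "green": 5}, roi_size=100
    )
    s = average_replicates([rep], patient_id="p1")
    df = samples_to_frame([s], groups=["bph"])
    assert list(df.patient_id) == ["p1"] and list(df.group) == ["bph"]
    assert df.loc[0, "prop_red"] == 0.5
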