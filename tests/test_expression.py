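import numpy as np
import pandas as pd
import pytest

from heptflux.expression import (
    Contrast,
    IntensityMatrix,
    call_differential,
    expression_ratio,
    filter_probes,
    floor_intensities,
    per_chip_median_normalize,
    process_expression,
    read_geo_series_matrix,
    read_intensity_tsv,
    write_intensity_tsv,
)
from heptflux.synthetic import ScenarioConfig, generate_intensity_matrix


def _matrix(values, flags=None, background=None, genes=None):
    """Small IntensityMatrix from a dict sample -> list of intensities."""
    intensity = pd.DataFrame(values, dtype=float)
    n = len(intensity)
    intensity.index = [f"p{i}" for i in range(n)]
    genes = genes or [f"g{i}" for i in range(n)]
    probes = pd.Series(genes, index=intensity.index)
    bg = pd.DataFrame(
        background if background is not None else 0.0,
        index=intensity.index,
        columns=intensity.columns,
        dtype=float,
    )
    fl = pd.DataFrame(
        flags if flags is not None else "P", index=intensity.index, columns=intensity.columns
    )
    return IntensityMatrix(probes=probes, intensity=intensity, background=bg, flags=fl)


class TestFloor:
    @pytest.mark.parametrize("raw,floored", [(4.9, 5.0), (5.0, 5.0), (1000.0, 1000.0)])
    def test_floor_rule(self, raw, floored):
        m = _matrix({"s1": [raw]})
        assert floor_intensities(m).intensity.iloc[0, 0] == floored

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            floor_intensities(_matrix({"s1": [10.0]}), floor=-1.0)


class TestMedianNormalize:
    def test_constant_chip_becomes_all_ones(self):
        m = _matrix({"s1": [7.0, 7.0, 7.0]})
        out = per_chip_median_normalize(m)
        assert (out.intensity["s1"] == 1.0).all()

    def test_hand_computed_chip(self):
        # chip [5, 10, 20], median 10 -> [0.5, 1, 2]
        m = _matrix({"s1": [5.0, 10.0, 20.0]})
        out = per_chip_median_normalize(m)
        assert out.intensity["s1"].tolist() == [0.5, 1.0, 2.0]

    def test_post_normalization_median_is_one_per_chip(self):
        cfg = ScenarioConfig(seed=3, noise_intensity_cv=0.2)
        m = per_chip_median_normalize(floor_intensities(generate_intensity_matrix(cfg)))
        for s in m.samples:
            assert m.intensity[s].median() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        m = _matrix({"s1": [5.0, 10.0, 20.0], "s2": [8.0, 2.0, 4.0]})
        once = per_chip_median_normalize(m)
        twice = per_chip_median_normalize(once)
        assert np.allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_zero_median_rejected(self):
        m = _matrix({"s1": [0.0, 0.0, 3.0]})
        with pytest.raises(ZeroDivisionError):
            per_chip_median_normalize(m)


class TestFilterProbes:
    def test_present_above_background_kept(self):
        m = _matrix({"s1": [10.0], "s2": [12.0]}, background=5.0)
        mask = filter_probes(m, Contrast(test=["s1"], control=["s2"]))
        assert mask.tolist() == [True]

    def test_marginal_flag_in_one_sample_drops_probe(self):
        m = _matrix(
            {"s1": [10.0], "s2": [12.0]},
            flags=pd.DataFrame({"s1": ["P"], "s2": ["M"]}, index=["p0"]),
        )
        mask = filter_probes(m, Contrast(test=["s1"], control=["s2"]))
        assert mask.tolist() == [False]

    def test_intensity_below_background_drops_probe(self):
        m = _matrix({"s1": [4.0], "s2": [12.0]}, background=6.0)
        mask = filter_probes(m, Contrast(test=["s1"], control=["s2"]))
        assert mask.tolist() == [False]

    def test_unknown_sample_rejected(self):
        m = _matrix({"s1": [4.0]})
        with pytest.raises(KeyError):
            filter_probes(m, Contrast(test=["s1"], control=["nope"]))


class TestExpressionRatio:
    def _norm(self, values, **kw):
        return per_chip_median_normalize(floor_intensities(_matrix(values, **kw)))

    def test_equal_means_give_unit_fold(self):
        m = self._norm({"t1": [5.0, 8.0], "c1": [5.0, 8.0]})
        rec = expression_ratio(m, Contrast(test=["t1"], control=["c1"]))
        assert rec["fold"].tolist() == [1.0, 1.0]
        assert rec["log2_ratio"].tolist() == [0.0, 0.0]

    def test_hand_arithmetic_fold_three(self):
        # normalized means: test 6, control 2 -> fold 3, log2 1.585
        m = _matrix({"t1": [6.0, 1.0], "c1": [2.0, 1.0]})
        m.normalized = True  # bypass: values are already on a common scale
        rec = expression_ratio(m, Contrast(test=["t1"], control=["c1"]))
        row = rec.set_index("gene").loc["g0"]
        assert row["fold"] == pytest.approx(3.0)
        assert row["log2_ratio"] == pytest.approx(np.log2(3.0), abs=1e-9)

    def test_log2_of_1p78_is_3p4_fold(self):
        """A planted log2 effect of 1.78 comes back as a 3.4-fold change
        (to one decimal), the published conversion for the hchA response."""
        cfg = ScenarioConfig(seed=5, de_truth={"hchA": 1.78}, noise_intensity_cv=0.0)
        m = generate_intensity_matrix(cfg)
        rec = process_expression(m, Contrast.from_conditions(m, "stressed", "control"))
        fold = rec.set_index("gene").loc["hchA", "fold"]
        assert round(fold, 1) == 3.4

    def test_requires_normalized_matrix(self):
        m = _matrix({"t1": [6.0], "c1": [2.0]})
        with pytest.raises(ValueError, match="normalized"):
            expression_ratio(m, Contrast(test=["t1"], control=["c1"]))

    def test_probe_to_gene_aggregation_by_mean(self):
        m = _matrix(
            {"t1": [4.0, 8.0], "c1": [2.0, 2.0]}, genes=["gx", "gx"]
        )
        m.normalized = True
        rec = expression_ratio(m, Contrast(test=["t1"], control=["c1"]))
        assert len(rec) == 1
        assert rec.loc[0, "fold"] == pytest.approx(6.0 / 2.0)

    def test_antisymmetry_under_contrast_swap(self):
        """Swapping test and control negates every log2 ratio exactly."""
        cfg = ScenarioConfig(
            seed=8, de_truth={"gadA": 2.27, "ompF": -1.5}, noise_intensity_cv=0.2
        )
        m = generate_intensity_matrix(cfg)
        fwd = process_expression(m, Contrast.from_conditions(m, "stressed", "control"))
        rev = process_expression(m, Contrast.from_conditions(m, "control", "stressed"))
        merged = fwd.merge(rev, on="gene", suffixes=("_f", "_r"))
        np.testing.assert_array_equal(
            merged["log2_ratio_f"].to_numpy(), -merged["log2_ratio_r"].to_numpy()
        )


class TestDifferentialCalls:
    @pytest.mark.parametrize(
        "fold,call", [(2.0, "up"), (0.5, "down"), (1.0, "none"), (3.7, "up"), (0.49, "down"), (1.99, "none")]
    )
    def test_two_fold_thresholds_inclusive(self, fold, call):
        rec = pd.DataFrame({"gene": ["g"], "fold": [fold]})
        assert call_differential(rec)["de_call"].iloc[0] == call

    def test_inverted_thresholds_rejected(self):
        rec = pd.DataFrame({"gene": ["g"], "fold": [1.0]})
        with pytest.raises(ValueError):
            call_differential(rec, up=0.5, down=2.0)


class TestPlantedEffectRecovery:
    def test_sensitivity_and_false_call_rate(self):
        """Planted 4-fold effects, log-normal noise CV 20%, 3 replicates per
        group: recall >= 0.9 on planted genes, false up/down calls <= 0.05
        among null genes, over 50 seeded runs."""
        planted = {"gadA": 2.0, "gadB": 2.0, "hdeA": 2.0, "hdeB": 2.0, "hchA": 2.0}
        hits = total = false = null_total = 0
        for seed in range(50):
            cfg = ScenarioConfig(
                seed=seed, de_truth=dict(planted), noise_intensity_cv=0.2, replicates=3
            )
            m = generate_intensity_matrix(cfg)
            rec = process_expression(
                m, Contrast.from_conditions(m, "stressed", "control")
            ).set_index("gene")
            for g in planted:
                total += 1
                hits += rec.loc[g, "de_call"] == "up"
            nulls = rec.drop(index=list(planted))
            null_total += len(nulls)
            false += (nulls["de_call"] != "none").sum()
        assert hits / total >= 0.9
        assert false / null_total <= 0.05


class TestIO:
    def test_intensity_tsv_round_trip(self, tmp_path):
        cfg = ScenarioConfig(
            seed=9, de_truth={"gadA": 1.0}, noise_intensity_cv=0.1,
            flag_absent_frac=0.05, n_genes=40,
        )
        m = generate_intensity_matrix(cfg)
        path = tmp_path / "intensity.tsv"
        write_intensity_tsv(m, path)
        back = read_intensity_tsv(path)
        assert back.conditions == m.conditions
        aligned = back.intensity.reindex(m.intensity.index)[m.samples]
        np.testing.assert_allclose(aligned.to_numpy(), m.intensity.to_numpy())
        flags = back.flags.reindex(m.flags.index)[m.samples]
        assert (flags.to_numpy() == m.flags.to_numpy()).all()

    def test_geo_series_matrix_reader(self, tmp_path):
        text = "\n".join(
            [
                '!Series_title\t"synthetic acid stress series"',
                '!Sample_geo_accession\t"GSM1"\t"GSM2"',
                '!Sample_title\t"control rep1"\t"stressed rep1"',
                "!series_matrix_table_begin",
                '"ID_REF"\t"GSM1"\t"GSM2"',
                '"gadA"\t1.0\t4.0',
                '"hdeB"\t2.0\t2.0',
                "!series_matrix_table_end",
                "",
            ]
        )
        path = tmp_path / "series_matrix.txt"
        path.write_text(text)
        m = read_geo_series_matrix(
            path, conditions={"control rep1": "control", "stressed rep1": "stressed"}
        )
        assert m.samples == ["GSM1", "GSM2"]
        assert m.conditions == {"GSM1": "control", "GSM2": "stressed"}
        assert m.intensity.loc["gadA", "GSM2"] == 4.0
        assert (m.flags == "P").all().all()

    def test_series_matrix_without_table_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("!Series_title\tnothing\n")
        with pytest.raises(ValueError, match="table"):
            read_geo_series_matrix(path)


class TestContrast:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            Contrast(test=["a"], control=["a"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            Contrast(test=[], control=["a"])
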