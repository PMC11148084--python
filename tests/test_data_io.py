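import numpy as np
import pandas as pd
import pytest

import saltscreen as ss
from saltscreen import data_io, indices, regression_model, tolerance_eval, trait_selector
from saltscreen.errors import (DegenerateInputError, IntegrityError, SchemaError,
                               ValidationError)


def write_csv(tmp_path, df, name="table.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def test_measurement_csv_round_trip(tmp_path, small_table):
    path = write_csv(tmp_path, small_table)
    again = ss.read_trait_table(path)
    pd.testing.assert_frame_equal(
        again.sort_values(list(data_io.KEY_COLUMNS), ignore_index=True),
        small_table.sort_values(list(data_io.KEY_COLUMNS), ignore_index=True))


def test_three_row_identity(tmp_path):
    df = pd.DataFrame(
        [("g1", 0.0, 1, "RL", 2.0), ("g1", 225.0, 1, "RL", 1.0),
         ("g1", 0.0, 2, "RL", 2.2)],
        columns=["genotype", "concentration", "replicate", "trait", "value"])
    assert len(ss.read_trait_table(write_csv(tmp_path, df))) == 3


def test_missing_column_named_in_schema_error(tmp_path):
    df = pd.DataFrame({"genotype": ["g1"], "concentration": [0.0],
                       "trait": ["RL"], "value": [1.0]})
    with pytest.raises(SchemaError, match="replicate"):
        ss.read_trait_table(write_csv(tmp_path, df))


def test_duplicate_key_rejected(tmp_path):
    df = pd.DataFrame(
        [("g1", 0.0, 1, "RL", 2.0), ("g1", 225.0, 1, "RL", 1.0),
         ("g1", 225.0, 1, "RL", 1.1)],
        columns=["genotype", "concentration", "replicate", "trait", "value"])
    with pytest.raises(IntegrityError, match="225"):
        ss.read_trait_table(write_csv(tmp_path, df))


@pytest.mark.parametrize("value", [-1.0, np.nan, "abc"])
def test_bad_values_rejected(tmp_path, value):
    df = pd.DataFrame(
        [("g1", 0.0, 1, "RL", 2.0), ("g1", 225.0, 1, "RL", value)],
        columns=["genotype", "concentration", "replicate", "trait", "value"])
    with pytest.raises(ValidationError):
        ss.read_trait_table(write_csv(tmp_path, df))


def test_unknown_trait_and_orphan_stress_rejected(tmp_path):
    bad_trait = pd.DataFrame(
        [("g1", 0.0, 1, "XYZ", 2.0)],
        columns=["genotype", "concentration", "replicate", "trait", "value"])
    with pytest.raises(ValidationError, match="XYZ"):
        ss.read_trait_table(write_csv(tmp_path, bad_trait))
    orphan = pd.DataFrame(
        [("g1", 0.0, 1, "RL", 2.0), ("g2", 225.0, 1, "RL", 1.0)],
        columns=["genotype", "concentration", "replicate", "trait", "value"])
    with pytest.raises(ValidationError, match="g2"):
        ss.read_trait_table(write_csv(tmp_path, orphan))


def test_germination_counts_convert_to_gr_rows(tmp_path):
    df = pd.DataFrame(
        [("g1", 0.0, 1, 15, 20), ("g1", 225.0, 1, 10, 20)],
        columns=["genotype", "concentration", "replicate",
                 "germinated_7das", "total_sown"])
    table = ss.read_trait_table(write_csv(tmp_path, df),
                                schema_mode="germination_counts")
    assert (table["trait"] == "GR").all()
    assert table.loc[table["concentration"] == 0.0, "value"].iloc[0] == 75.0


def test_wide_importer_melts_trait_columns(tmp_path):
    df = pd.DataFrame({
        "genotype": ["g1", "g1"], "concentration": [0.0, 225.0],
        "replicate": [1, 1], "RL": [2.0, 1.0], "SFW": [20.0, 9.0]})
    table = ss.read_wide_table(write_csv(tmp_path, df))
    assert set(table["trait"]) == {"RL", "SFW"}
    assert len(table) == 4


def test_write_report_round_trips(tmp_path, small_table):
    idx = ss.build_index_table(small_table)
    path = tmp_path / "idx.csv"
    ss.write_report(idx, path)
    again = pd.read_csv(path)
    assert np.allclose(again["sti"], idx["sti"])

    rng = np.random.default_rng(17)
    sti = pd.DataFrame({"RL": rng.uniform(0, 1, 10)},
                       index=[f"g{i}" for i in range(10)])
    scores = pd.Series(0.3 + 0.5 * sti["RL"] + rng.normal(0, 0.02, 10),
                       index=sti.index)
    model = regression_model.fit_model(sti, scores, ("RL",))
    mpath = tmp_path / "model.json"
    ss.write_report(model, mpath)
    clone = data_io.read_model(mpath)
    assert abs(clone.mu - model.mu) < 1e-12

    with pytest.raises(IOError):
        ss.write_report(idx, tmp_path / "no_such_dir" / "x.csv")
    with pytest.raises(TypeError):
        ss.write_report(object(), tmp_path / "x.json")


def test_config_yaml_round_trip_and_validation(tmp_path):
    cfg = data_io.PipelineConfig(cluster_count=4, target_sii=0.4,
                                 traits_for_model=("SFW", "SDW"))
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    clone = data_io.PipelineConfig.from_yaml(path)
    assert clone == cfg
    (tmp_path / "bad.yaml").write_text("no_such_key: 1\n")
    with pytest.raises(SchemaError):
        data_io.PipelineConfig.from_yaml(tmp_path / "bad.yaml")
    with pytest.raises(ValidationError):
        data_io.PipelineConfig(cluster_count=1)
    with pytest.raises(ValidationError):
        data_io.PipelineConfig(target_sii=1.5)
    with pytest.raises(ValueError):
        data_io.PipelineConfig(traits_for_model=())


def test_pipeline_equals_stage_by_stage_composition():
    table, _ = ss.generate(ss.SyntheticConfig(random_seed=42))
    cfg = data_io.PipelineConfig()
    result = ss.run_pipeline(table, cfg)
    assert len(result.tolerance_report.table) == 59

    idx = indices.build_index_table(table, cfg.replicate_aggregator, cfg.sti_mode)
    pd.testing.assert_frame_equal(result.index_table, idx)
    _, _, optimum = ss.find_optimum_dose(idx, cfg.tested_concentrations,
                                         cfg.target_sii)
    assert result.screening_concentration == optimum.chosen_concentration
    at_dose = idx[idx["concentration"] == optimum.chosen_concentration]
    _, scores, report = tolerance_eval.evaluate_tolerance(
        at_dose, cfg.traits_for_mean_mfv, cfg.cluster_count)
    pd.testing.assert_frame_equal(result.tolerance_report.table, report.table)
    sti = trait_selector.sti_pivot(indices.apply_undefined_policy(at_dose))
    model = regression_model.fit_model(sti, scores, cfg.traits_for_model)
    assert result.model.mu == model.mu
    for t in model.traits:
        assert result.model.coefficients[t].beta == model.coefficients[t].beta


def test_pipeline_single_genotype_fails_in_mfv_stage():
    rows = [("g1", c, r, t, v)
            for c, v in ((0.0, 4.0), (225.0, 2.0)) for r in (1, 2)
            for t in ("RL", "SFW")]
    table = pd.DataFrame(rows, columns=["genotype", "concentration", "replicate",
                                        "trait", "value"])
    cfg = data_io.PipelineConfig(traits_for_mean_mfv=("RL", "SFW"),
                                 traits_for_model=("RL", "SFW"))
    with pytest.raises(DegenerateInputError, match="tolerance_eval"):
        ss.run_pipeline(table, cfg)


def test_pipeline_reduced_model_traits():
    table, _ = ss.generate(ss.screening_config(random_seed=2, n_genotypes=20))
    cfg = data_io.PipelineConfig(traits_for_model=("SFW",))
    result = ss.run_pipeline(table, cfg)
    assert tuple(result.model.coefficients) == ("SFW",)
    assert result.screening_concentration == 225.0  # single stress dose used as-is
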