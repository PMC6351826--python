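"""Clock engine: file round trips, age transform, prediction, per-CpG tracks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rejuvotrack.clocks import (
    BetaMatrix,
    ClockFormatError,
    ClockSpec,
    MissingProbeError,
    extract_cpg_trajectory,
    forward_transform,
    inverse_transform,
    load_clock,
    predict_age,
    write_clock,
)


# ---------------------------------------------------------------------------
# clock files


def test_clock_file_round_trip(tmp_path, tiny_identity_clock):
    path = tmp_path / "clock.txt"
    write_clock(tiny_identity_clock, path)
    loaded = load_clock(path)
    assert loaded == tiny_identity_clock


def test_three_probe_toy_clock_file(tmp_path):
    path = tmp_path / "c.txt"
    path.write_text(
        "#name=demo\n#intercept=0.5\n#transform=identity\n"
        "cg1,0.1\ncg2,-0.2\ncg3,0.3\n"
    )
    clock = load_clock(path)
    assert len(clock.coefficients) == 3 and clock.intercept == 0.5


@pytest.mark.parametrize(
    "content,match",
    [
        ("#name=x\n#intercept=0\n#transform=log-linear\ncg1,1\n", "adult_age"),
        ("#name=x\n#intercept=0\n#transform=identity\ncg1,1\ncg1,2\n", "duplicate"),
        ("#name=x\n#transform=identity\ncg1,1\n", "intercept"),
        ("#name=x\n#intercept=zzz\n#transform=identity\ncg1,1\n", "intercept"),
        ("#name=x\n#intercept=0\n#transform=cubic\ncg1,1\n", "transform"),
    ],
)
def test_malformed_clock_files_name_the_field(tmp_path, content, match):
    path = tmp_path / "bad.txt"
    path.write_text(content)
    with pytest.raises(ClockFormatError, match=match):
        load_clock(path)


def test_clockspec_invariants():
    with pytest.raises(ClockFormatError):
        ClockSpec("empty", 0.0, {}, "identity", None)
    with pytest.raises(ClockFormatError):
        ClockSpec("bad", 0.0, {"cg1": np.inf}, "identity", None)
    with pytest.raises(ClockFormatError):
        ClockSpec("bad", 0.0, {"cg1": 1.0}, "log-linear", -3.0)


# ---------------------------------------------------------------------------
# age transform


@pytest.mark.parametrize(
    "age,adult,expected",
    [
        (20, 20, 0.0),
        (0, 20, -math.log(21)),
        (41, 20, 1.0),
    ],
)
def test_forward_transform_values(age, adult, expected):
    assert forward_transform(age, adult) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "x,adult,expected",
    [(0.0, 20, 20.0), (1.0, 20, 41.0), (-math.log(21), 20, 0.0)],
)
def test_inverse_transform_values(x, adult, expected):
    assert inverse_transform(x, adult) == pytest.approx(expected, abs=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    age=st.floats(min_value=-0.999, max_value=120.0),
    adult=st.floats(min_value=1.0, max_value=60.0),
)
def test_transform_round_trip(age, adult):
    assert inverse_transform(forward_transform(age, adult), adult) == pytest.approx(
        age, rel=1e-9, abs=1e-9
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    x=st.floats(min_value=-5.0, max_value=5.0),
    adult=st.floats(min_value=1.0, max_value=60.0),
)
def test_transform_round_trip_from_transformed_scale(x, adult):
    assert forward_transform(inverse_transform(x, adult), adult) == pytest.approx(
        x, rel=1e-9, abs=1e-9
    )


def test_forward_transform_domain_and_monotonicity():
    with pytest.raises(ValueError):
        forward_transform(-1.0, 20)
    ages = np.linspace(-0.99, 119, 400)
    assert np.all(np.diff(forward_transform(ages, 20)) > 0)


# ---------------------------------------------------------------------------
# prediction


def _brute_force_eage(clock, betas_df):
    """Independent per-sample loop: the oracle for predict_age."""
    out = {}
    for sample in betas_df.columns:
        score = clock.intercept
        for probe, weight in clock.coefficients.items():
            score += weight * betas_df.loc[probe, sample]
        if clock.transform == "log-linear":
            if score <= 0:
                age = (clock.adult_age + 1) * math.exp(score) - 1
            else:
                age = clock.adult_age + score * (clock.adult_age + 1)
        else:
            age = score
        out[sample] = age
    return out


def test_zero_weight_loglinear_clock_predicts_adult_age():
    clock = ClockSpec("zero", 0.0, {"cg1": 0.0, "cg2": 0.0}, "log-linear", 20.0)
    betas = BetaMatrix(pd.DataFrame({"s1": [0.1, 0.9], "s2": [0.5, 0.5]}, index=["cg1", "cg2"]))
    out = predict_age(clock, betas)
    assert out["eage"].to_numpy() == pytest.approx([20.0, 20.0])


def test_single_probe_identity_clock():
    clock = ClockSpec("one", 0.2, {"cg1": 1.0}, "identity", None)
    betas = BetaMatrix(pd.DataFrame({"s": [0.5]}, index=["cg1"]))
    assert predict_age(clock, betas)["eage"].iloc[0] == pytest.approx(0.7)


@pytest.mark.parametrize("transform", ["identity", "log-linear"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_predict_age_matches_brute_force(transform, seed):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i}" for i in range(7)]
    clock = ClockSpec(
        "rand",
        float(rng.normal()),
        dict(zip(probes, rng.normal(0, 0.4, 7).tolist())),
        transform,
        20.0 if transform == "log-linear" else None,
    )
    betas = BetaMatrix(
        pd.DataFrame(rng.uniform(0, 1, (7, 4)), index=probes, columns=list("abcd"))
    )
    got = predict_age(clock, betas).set_index("sample")["eage"]
    expected = _brute_force_eage(clock, betas.values)
    for sample, age in expected.items():
        assert got[sample] == pytest.approx(age, abs=1e-10)


def test_increasing_beta_with_positive_weight_never_decreases_eage():
    clock = ClockSpec("mono", -0.3, {"cg1": 0.8, "cg2": -0.4}, "log-linear", 20.0)
    base = pd.DataFrame({"s": [0.3, 0.6]}, index=["cg1", "cg2"])
    ages = []
    for b in np.linspace(0.3, 1.0, 15):
        df = base.copy()
        df.loc["cg1", "s"] = b
        ages.append(predict_age(clock, BetaMatrix(df))["eage"].iloc[0])
    assert np.all(np.diff(ages) >= 0)


def test_missing_policies_agree_when_nothing_is_missing(tiny_identity_clock):
    rng = np.random.default_rng(3)
    betas = BetaMatrix(
        pd.DataFrame(
            rng.uniform(0, 1, (5, 3)),
            index=list(tiny_identity_clock.coefficients),
            columns=["a", "b", "c"],
        )
    )
    ref = pd.Series(0.5, index=tiny_identity_clock.probes)
    outs = [
        predict_age(tiny_identity_clock, betas, policy, reference=ref)
        for policy in ("error", "impute_half", "impute_reference")
    ]
    for other in outs[1:]:
        pd.testing.assert_frame_equal(outs[0], other)


def test_missing_probe_handling(tiny_identity_clock):
    betas = BetaMatrix(
        pd.DataFrame(
            {"s1": [0.2, 0.4], "s2": [np.nan, 0.6]}, index=["cg000", "cg001"]
        )
    )
    with pytest.raises(MissingProbeError) as err:
        predict_age(tiny_identity_clock, betas, "error")
    assert "cg002" in str(err.value)

    out = predict_age(tiny_identity_clock, betas, "impute_half")
    # s1 misses 3 absent probes; s2 additionally misses the NaN call
    assert out.set_index("sample")["n_missing_probes"].tolist() == [3, 4]
    expected_s1 = 0.2 + 0.2 * 1.0 + 0.4 * -0.5 + 0.5 * (2.0 + 0.0 + 0.75)
    assert out.set_index("sample").loc["s1", "eage"] == pytest.approx(expected_s1)

    ref = pd.Series({"cg002": 0.1, "cg003": 0.2, "cg004": 0.3, "cg000": 0.9})
    out_ref = predict_age(tiny_identity_clock, betas, "impute_reference", reference=ref)
    expected_ref_s1 = 0.2 + 0.2 * 1.0 + 0.4 * -0.5 + 0.1 * 2.0 + 0.2 * 0.0 + 0.3 * 0.75
    assert out_ref.set_index("sample").loc["s1", "eage"] == pytest.approx(expected_ref_s1)


def test_all_probes_missing_for_a_sample_is_an_error(tiny_identity_clock):
    betas = BetaMatrix(
        pd.DataFrame(
            {"ok": [0.2] * 5, "empty": [np.nan] * 5},
            index=list(tiny_identity_clock.coefficients),
        )
    )
    with pytest.raises(ValueError, match="empty"):
        predict_age(tiny_identity_clock, betas, "impute_half")


# ---------------------------------------------------------------------------
# beta matrix validation


def test_beta_matrix_rejects_mvalues_and_clips_tolerance():
    with pytest.raises(ValueError, match="M-values"):
        BetaMatrix(pd.DataFrame({"s": [1.5]}, index=["cg1"]))
    bm = BetaMatrix(pd.DataFrame({"s": [1.0 + 5e-7, -5e-7]}, index=["cg1", "cg2"]))
    assert bm.values["s"].tolist() == [1.0, 0.0]


def test_beta_matrix_rejects_duplicate_ids():
    with pytest.raises(ValueError, match="probe"):
        BetaMatrix(pd.DataFrame([[0.1], [0.2]], index=["cg1", "cg1"], columns=["s"]))


def test_beta_matrix_csv_round_trip(tmp_path):
    df = pd.DataFrame({"s1": [0.1, np.nan], "s2": [0.3, 0.4]}, index=["cg1", "cg2"])
    bm = BetaMatrix(df)
    path = tmp_path / "betas.csv"
    bm.to_csv(path)
    back = BetaMatrix.read_csv(path)
    pd.testing.assert_frame_equal(back.values, bm.values)


# ---------------------------------------------------------------------------
# single-CpG trajectories


def test_constant_probe_trajectory(simple_sheet):
    betas = BetaMatrix(
        pd.DataFrame([[0.8, 0.8, 0.8]], index=["cg9"], columns=simple_sheet["sample"])
    )
    out = extract_cpg_trajectory(betas, "cg9", simple_sheet)
    assert (out["mean"] == 0.8).all() and (out["sd"] == 0).all() and (out["n"] == 1).all()


def test_two_replicate_mean_and_missing_probe():
    sheet = pd.DataFrame(
        {"sample": ["a", "b"], "day": [7.0, 7.0], "replicate": ["r1", "r2"]}
    )
    betas = BetaMatrix(pd.DataFrame([[0.4, 0.6]], index=["cg1"], columns=["a", "b"]))
    out = extract_cpg_trajectory(betas, "cg1", sheet)
    assert out["mean"].iloc[0] == pytest.approx(0.5)
    assert out["n"].iloc[0] == 2
    with pytest.raises(MissingProbeError):
        extract_cpg_trajectory(betas, "cg_absent", sheet)


def test_declining_probe_tracks_generator_truth(toy_clock):
    from rejuvotrack import simulate as sim

    spec = sim.TrajectorySpec(noise_sd_age=0.0, noise_sd_beta=0.0, seed=5)
    betas, sheet, _ = sim.synth_beta_course(toy_clock, spec)
    # pick the largest-|weight| probe: its beta moves most along the trajectory
    probe = max(toy_clock.coefficients, key=lambda p: abs(toy_clock.coefficients[p]))
    out = extract_cpg_trajectory(betas, probe, sheet)
    assert sorted(out["day"]) == list(out["day"])
    # noise-free: replicates identical, so per-day SD is 0 and means are monotone
    # in the direction of the weight for the declining phase
    assert out["sd"].to_numpy() == pytest.approx(0.0, abs=1e-12)
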