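import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from paleodiv import compare_all, partition_exact, partition_rarefied, validate_frame
from paleodiv.incidence import Stratum, StratumKey


def _bruteforce(A, B):
    """Independent oracle: element-by-element set arithmetic."""
    a = sum(1 for t in A if t in B)
    b = sum(1 for t in A if t not in B)
    c = sum(1 for t in B if t not in A)
    bsor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    bsim = m / (a + m) if a + m else 0.0
    return bsor, bsim, bsor - bsim


class TestExactPartition:
    def test_identity_pair_is_zero(self):
        p = partition_exact({"a", "b"}, {"a", "b"})
        assert (p.beta_sor, p.beta_sim, p.beta_nes) == (0.0, 0.0, 0.0)

    def test_disjoint_pair_is_pure_turnover(self):
        p = partition_exact({"a", "b"}, {"c", "d", "e"})
        assert (p.beta_sor, p.beta_sim, p.beta_nes) == (1.0, 1.0, 0.0)

    def test_worked_pair(self):
        p = partition_exact({"s1", "s2", "s3"}, {"s2", "s3", "s4", "s5"})
        assert (p.a_shared, p.b_only, p.c_only) == (2, 1, 2)
        assert p.beta_sor == pytest.approx(3 / 7)
        assert p.beta_sim == pytest.approx(1 / 3)
        assert p.beta_nes == pytest.approx(2 / 21)

    def test_strict_subset_is_pure_nestedness(self):
        p = partition_exact({"s1", "s2"}, {"s1", "s2", "s3", "s4"})
        assert p.beta_sim == 0.0
        assert p.beta_sor == pytest.approx(1 / 3)
        assert p.beta_nes == pytest.approx(p.beta_sor)

    def test_empty_assemblage_is_error(self):
        with pytest.raises(ValueError):
            partition_exact(set(), {"a"})

    def test_random_pools_match_bruteforce(self):
        rng = np.random.default_rng(7)
        universe = [f"t{i}" for i in range(60)]
        for _ in range(300):
            A = set(rng.choice(universe, size=rng.integers(1, 31), replace=False))
            B = set(rng.choice(universe, size=rng.integers(1, 31), replace=False))
            p = partition_exact(A, B)
            bsor, bsim, bnes = _bruteforce(A, B)
            assert (p.beta_sor, p.beta_sim) == (bsor, bsim)
            assert p.beta_nes == pytest.approx(bnes, abs=1e-15)
            assert abs(p.beta_sor - p.beta_sim - p.beta_nes) <= 1e-12


@given(
    A=st.sets(st.integers(0, 40), min_size=1, max_size=30),
    B=st.sets(st.integers(0, 40), min_size=1, max_size=30),
)
def test_property_symmetry_additivity_bounds(A, B):
    p = partition_exact(A, B)
    q = partition_exact(B, A)
    assert (p.beta_sor, p.beta_sim, p.beta_nes) == (q.beta_sor, q.beta_sim, q.beta_nes)
    assert 0 <= p.beta_sim <= p.beta_sor <= 1
    assert p.beta_nes >= 0
    assert abs(p.beta_sor - p.beta_sim - p.beta_nes) <= 1e-12
    if p.b_only == p.c_only:
        assert p.beta_nes == pytest.approx(0, abs=1e-12)


def _stratum(taxa, interval="tortonian"):
    return Stratum(StratumKey("ostracods", interval), np.array(taxa, dtype=object))


class TestRarefiedPartition:
    def test_identical_lists_full_quota_all_zero(self):
        taxa = [f"t{i}" for i in range(20)]
        part, reps = partition_rarefied(
            _stratum(taxa), _stratum(taxa, "zanclean"),
            fraction=1.0, replicates=30, seed=1,
        )
        assert (reps[["beta_sor", "beta_sim", "beta_nes"]].to_numpy() == 0).all()
        assert part.beta_sor == 0.0

    def test_disjoint_pools_all_one(self):
        a = [f"a{i}" for i in range(20)]
        b = [f"b{i}" for i in range(20)]
        part, reps = partition_rarefied(
            _stratum(a), _stratum(b, "zanclean"), replicates=30, seed=1
        )
        assert (reps["beta_sor"] == 1).all() and (reps["beta_sim"] == 1).all()
        assert part.beta_nes == 0.0

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(0)
        a = rng.choice([f"t{i}" for i in range(30)], size=40).tolist()
        b = rng.choice([f"t{i}" for i in range(20, 50)], size=40).tolist()
        p1, r1 = partition_rarefied(
            _stratum(a), _stratum(b, "zanclean"), replicates=50, seed=12
        )
        p2, r2 = partition_rarefied(
            _stratum(a), _stratum(b, "zanclean"), replicates=50, seed=12
        )
        pd.testing.assert_frame_equal(r1, r2)
        assert p1.beta_sim == p2.beta_sim

    def test_additivity_holds_per_replicate(self):
        rng = np.random.default_rng(1)
        a = rng.choice([f"t{i}" for i in range(25)], size=40).tolist()
        b = rng.choice([f"t{i}" for i in range(15, 40)], size=40).tolist()
        _, reps = partition_rarefied(
            _stratum(a), _stratum(b, "zanclean"), replicates=100, seed=3
        )
        resid = (reps["beta_sor"] - reps["beta_sim"] - reps["beta_nes"]).abs()
        assert resid.max() <= 1e-12


def _pool_dataset():
    """Known interval pools, 20 occurrences per stratum (2 localities/taxon)."""
    pools = {
        "tortonian": [f"t{i}" for i in range(10)],
        "messinian_pre_evaporitic": [f"t{i}" for i in range(5, 15)],
        "zanclean": [f"t{i}" for i in range(10, 20)],
    }
    rows = []
    for iv, taxa in pools.items():
        for t in taxa:
            for loc in ("LA", "LB"):
                rows.append(
                    {
                        "taxon_name": f"Gen{t} sp1",
                        "rank": "species",
                        "genus": f"Gen{t}",
                        "group": "bryozoans",
                        "locality_id": loc,
                        "region": "western_mediterranean",
                        "interval": iv,
                        "reworked": "false",
                        "coral_ecology": "",
                    }
                )
    return validate_frame(pd.DataFrame(rows)), pools


class TestCompareAll:
    def test_exact_indices_match_set_arithmetic(self):
        ds, pools = _pool_dataset()
        tab = compare_all(ds, "bryozoans", mode="exact")
        assert (tab["status"] == "ok").all()
        for _, row in tab.iterrows():
            iv_a, iv_b = row["pair"].split("–")
            A = {f"Gen{t} sp1" for t in pools[iv_a]}
            B = {f"Gen{t} sp1" for t in pools[iv_b]}
            bsor, bsim, bnes = _bruteforce(A, B)
            assert row["beta_sor"] == pytest.approx(bsor)
            assert row["beta_sim"] == pytest.approx(bsim)
            assert row["beta_nes"] == pytest.approx(bnes)

    def test_swapped_interval_order_is_symmetric(self):
        ds, _ = _pool_dataset()
        fwd = compare_all(ds, "bryozoans", mode="exact")
        rev = compare_all(
            ds,
            "bryozoans",
            interval_pairs=[("messinian_pre_evaporitic", "tortonian")],
            mode="exact",
        )
        t_m = fwd[fwd["pair"] == "tortonian–messinian_pre_evaporitic"]
        assert rev["beta_sor"].iloc[0] == pytest.approx(t_m["beta_sor"].iloc[0])
        assert rev["beta_sim"].iloc[0] == pytest.approx(t_m["beta_sim"].iloc[0])

    def test_missing_interval_flagged_not_dropped(self):
        ds, _ = _pool_dataset()
        only_t = validate_frame(
            ds.frame[ds.frame["interval"] == "tortonian"].astype(str)
        )
        tab = compare_all(only_t, "bryozoans")
        assert len(tab) == 3
        assert (tab["status"] != "ok").all()
        assert tab["beta_sor"].isna().all()
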