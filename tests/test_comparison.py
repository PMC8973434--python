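import math

import numpy as np
import pandas as pd
import pytest

from nampod.comparison import (chemotype_enrichment, harmonize_response_type,
                               protectiveness_summary, select_traditional_pod)


def fisher_greater_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher p by exhaustive hypergeometric enumeration."""
    r1, k1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, k1)
    return sum(math.comb(r1, x) * math.comb(n - r1, k1 - x)
               for x in range(a, min(r1, k1) + 1)) / denom


def holm_oracle(pvals):
    """Independent Holm step-down implementation."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestHarmonize:
    @pytest.mark.parametrize("raw,expected", [
        ("NOEC", "NOAEL"), ("NOAEC", "NOAEL"), ("NOEL", "NOAEL"), ("NEL", "NOAEL"),
        ("HNEL", "NOAEL"), ("LOEC", "LOAEL"), ("LOAEC", "LOAEL"), ("LOEL", "LOAEL"),
        ("LEL", "LOAEL"), ("NOAEL", "NOAEL"), ("LOAEL", "LOAEL"), ("BMDL", "BMDL"),
        ("noec", "NOAEL"),  # case-insensitive
    ])
    def test_synonym_mapping(self, raw, expected):
        assert harmonize_response_type(raw) == expected

    @pytest.mark.parametrize("raw", ["LD50", "BMD", "", None, "NOAELX"])
    def test_rejection(self, raw):
        assert harmonize_response_type(raw) is None


def trad_row(value, units="mg/kg-day", route="oral", study="chronic", rtype="NOAEL"):
    return dict(chem_id="c1", toxval_numeric=value, toxval_units=units,
                exposure_route=route, study_type=study, toxval_type=rtype)


class TestSelectTraditionalPod:
    def test_min_of_surviving_records(self):
        records = pd.DataFrame([
            trad_row(10, route="oral", study="subchronic"),
            trad_row(3, route="gavage", rtype="LOAEL"),
            trad_row(5, route="dermal"),  # excluded by route
        ])
        assert select_traditional_pod(records) == 3.0

    def test_wrong_units_yield_absent(self):
        records = pd.DataFrame([trad_row(10, units="ppm"), trad_row(5, units="mg/m3")])
        assert select_traditional_pod(records) is None

    def test_empty_input_absent(self):
        assert select_traditional_pod(pd.DataFrame(columns=list(trad_row(1)))) is None

    def test_unit_dialects_accepted(self):
        for units in ("mg/kg", "mg/kg-day", "mg/kg/day", "MG/KG BW/DAY"):
            assert select_traditional_pod(pd.DataFrame([trad_row(2, units=units)])) == 2.0

    def test_study_type_restriction(self):
        assert select_traditional_pod(pd.DataFrame([trad_row(1, study="acute")])) is None

    def test_never_exceeds_minimum_of_survivors(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame([trad_row(v) for v in rng.lognormal(1, 1, 20)])
        assert select_traditional_pod(records) == records["toxval_numeric"].min()


class TestProtectiveness:
    def test_protective_flag_and_log_ratio(self):
        nam = pd.Series({"a": 1.0, "b": 5.0, "c": 10.0})
        trad = pd.Series({"a": 100.0, "b": 5.0, "c": 1.0})
        out = protectiveness_summary(nam, trad)
        per = out.per_chemical.set_index("chem_id")
        assert per.loc["a", "protective"] and per.loc["a", "log10_ratio"] == pytest.approx(2.0)
        assert per.loc["b", "protective"]  # equality counts as protective
        assert not per.loc["c", "protective"]
        assert per.loc["c", "log10_ratio"] == pytest.approx(-1.0)
        assert out.fraction_protective == pytest.approx(2 / 3)

    def test_median_fold_on_arithmetic_scale(self):
        nam = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        trad = pd.Series({"a": 10.0, "b": 100.0, "c": 1000.0})
        assert protectiveness_summary(nam, trad).median_fold_difference == pytest.approx(100.0)

    def test_no_pairs_is_error(self):
        with pytest.raises(ValueError):
            protectiveness_summary(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestEnrichment:
    def make_fps(self, bits_by_chem):
        return pd.DataFrame.from_dict(bits_by_chem, orient="index").astype(np.uint8)

    def test_no_enrichment_signal_p_one(self):
        # bit never set in the non-protective group: the one-sided tail
        # covers the whole support, p = 1 exactly
        fps = self.make_fps({f"c{i}": {"bit": int(i >= 4)} for i in range(8)})
        out = chemotype_enrichment(["c0", "c1"], [f"c{i}" for i in range(8)], fps)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert not out.loc[0, "enriched"]

    def test_equal_proportions_never_significant(self):
        # bit set in the same proportion in both groups carries no signal
        fps = self.make_fps({f"c{i}": {"bit": int(i % 2 == 0)} for i in range(8)})
        out = chemotype_enrichment(["c0", "c1"], [f"c{i}" for i in range(8)], fps)
        assert out.loc[0, "p"] == pytest.approx(
            fisher_greater_oracle(1, 1, 3, 3), rel=1e-12)
        assert not out.loc[0, "enriched"]

    def test_worked_contingency_table_matches_enumeration(self):
        # a=5 (non-protective, bit set), b=1, c=2, d=12
        chems = [f"n{i}" for i in range(6)] + [f"r{i}" for i in range(14)]
        bits = {c: {"bit": 1} for c in chems[:5]}
        bits |= {chems[5]: {"bit": 0}}
        bits |= {c: {"bit": 1} for c in chems[6:8]}
        bits |= {c: {"bit": 0} for c in chems[8:]}
        fps = self.make_fps(bits)
        out = chemotype_enrichment(chems[:6], chems, fps)
        assert (out.loc[0, ["a", "b", "c", "d"]].tolist() == [5, 1, 2, 12])
        assert out.loc[0, "p"] == pytest.approx(fisher_greater_oracle(5, 1, 2, 12), rel=1e-12)

    def test_single_test_holm_equals_raw(self):
        fps = self.make_fps({"a": {"bit": 1}, "b": {"bit": 0}, "c": {"bit": 1}, "d": {"bit": 0}})
        out = chemotype_enrichment(["a"], ["a", "b", "c", "d"], fps)
        assert out.loc[0, "p_holm"] == pytest.approx(out.loc[0, "p"])

    def test_holm_monotone_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        n = 40
        chems = [f"c{i}" for i in range(n)]
        fps = pd.DataFrame((rng.random((n, 12)) < 0.4).astype(np.uint8), index=chems,
                           columns=[f"bit_{j}" for j in range(12)])
        nonprot = chems[:8]
        out = chemotype_enrichment(nonprot, chems, fps)
        assert (out["p_holm"] >= out["p"] - 1e-15).all()
        expected = holm_oracle(out["p"].to_numpy())
        assert np.allclose(out["p_holm"].to_numpy(), expected, atol=1e-12)

    def test_zero_variance_bits_skipped(self):
        fps = self.make_fps({"a": {"on": 1, "off": 0}, "b": {"on": 1, "off": 0}})
        out = chemotype_enrichment(["a"], ["a", "b"], fps)
        assert len(out) == 0

    def test_missing_fingerprint_raises(self):
        fps = self.make_fps({"a": {"bit": 1}})
        with pytest.raises(ValueError, match="missing"):
            chemotype_enrichment(["a"], ["a", "ghost"], fps)
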