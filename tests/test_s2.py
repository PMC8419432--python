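"""Round-two classifier, consensus merge, summaries and keyword census."""

import itertools

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_evidence
from nucsort.domains import ProteinDomainAttribute
from nucsort.evidence import EvidenceConfig
from nucsort.model import UniProtState
from nucsort.s1 import S1Category
from nucsort.s2 import (
    ConsensusCall,
    FinalLabel,
    S2Category,
    S2_NUCLEAR_SIDE,
    classify_s2,
    keyword_census,
    merge_s1_s2,
    percent_one_decimal,
    summarize_categories,
)

CFG = EvidenceConfig()
STATES = (UniProtState.NUCLEAR, UniProtState.NON_NUCLEAR, UniProtState.ABSENT)
DS = tuple(ProteinDomainAttribute)


def s2_rule_table(
    n: int, horvu: UniProtState, arath: UniProtState, ds: ProteinDomainAttribute
) -> S2Category:
    """Independent oracle: flat decision list for the stricter round."""
    if ds == ProteinDomainAttribute.NO_DOMAIN_INFO:
        return S2Category.UNSUFFICIENT_CD_INFO
    hn = horvu == UniProtState.NUCLEAR
    an = arath == UniProtState.NUCLEAR
    if n == 4 and ds == ProteinDomainAttribute.TRUE and hn:
        return S2Category.NUCLEAR
    if n == 4 and ds == ProteinDomainAttribute.TRUE and not hn and an:
        return S2Category.NUCLEAR_BLAST
    if n <= 2 and (hn or an):
        return S2Category.POSSIBLY_NUCLEAR
    if not hn and not an and n >= 2:
        return S2Category.DISCREPANCY_UNIPROT
    return S2Category.NON_NUCLEAR


FULL_SPACE = list(itertools.product(range(5), STATES, STATES, DS))


def test_agrees_with_rule_table_on_full_space():
    assert len(FULL_SPACE) == 180
    for n, horvu, arath, ds in FULL_SPACE:
        ev = make_evidence(n, horvu, arath)
        got = classify_s2(ev, ds, CFG)
        want = s2_rule_table(n, horvu, arath, ds)
        assert got is want, f"({n}, {horvu}, {arath}, {ds}): {got} != {want}"


@pytest.mark.parametrize(
    "n,horvu,arath,ds,expected",
    [
        (4, UniProtState.NUCLEAR, UniProtState.ABSENT, ProteinDomainAttribute.TRUE,
         S2Category.NUCLEAR),
        (4, UniProtState.ABSENT, UniProtState.NUCLEAR, ProteinDomainAttribute.TRUE,
         S2Category.NUCLEAR_BLAST),
        (4, UniProtState.NUCLEAR, UniProtState.ABSENT,
         ProteinDomainAttribute.NO_DOMAIN_INFO, S2Category.UNSUFFICIENT_CD_INFO),
        (2, UniProtState.NUCLEAR, UniProtState.ABSENT, ProteinDomainAttribute.TRUE,
         S2Category.POSSIBLY_NUCLEAR),
        (4, UniProtState.NON_NUCLEAR, UniProtState.NON_NUCLEAR,
         ProteinDomainAttribute.TRUE, S2Category.DISCREPANCY_UNIPROT),
        # a vote of exactly three satisfies neither "more than three" nor
        # "less than three" and falls through
        (3, UniProtState.NUCLEAR, UniProtState.ABSENT, ProteinDomainAttribute.TRUE,
         S2Category.NON_NUCLEAR),
    ],
)
def test_worked_examples(n, horvu, arath, ds, expected):
    assert classify_s2(make_evidence(n, horvu, arath), ds, CFG) is expected


def test_widened_strong_threshold_promotes_three_votes():
    from dataclasses import replace

    cfg3 = replace(CFG, s2_strong_hit_min=3)
    ev = make_evidence(3, UniProtState.NUCLEAR)
    assert classify_s2(ev, ProteinDomainAttribute.TRUE, cfg3) is S2Category.NUCLEAR


class TestMerge:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            (S1Category.NUCLEAR, S2Category.NUCLEAR, FinalLabel.NUCLEAR_S1_AND_S2),
            (S1Category.DISCREPANCY_UNIPROT, S2Category.POSSIBLY_NUCLEAR,
             FinalLabel.NUCLEAR_S1_AND_S2),
            (S1Category.NUCLEAR, S2Category.UNSUFFICIENT_CD_INFO,
             FinalLabel.NUCLEAR_S1_EXTRA),
            (S1Category.CYTOSOLIC, S2Category.NON_NUCLEAR, FinalLabel.NON_NUCLEAR),
            (S1Category.NON_CLASSIFIED, S2Category.NUCLEAR, FinalLabel.NON_NUCLEAR),
        ],
    )
    def test_examples(self, s1, s2, expected):
        assert merge_s1_s2(s1, s2) is expected

    def test_count_identity_over_full_product(self):
        from nucsort.s1 import S1_NUCLEAR_SIDE

        pairs = list(itertools.product(S1Category, S2Category))
        labels = [merge_s1_s2(a, b) for a, b in pairs]
        n_nuclear_side = sum(1 for a, _ in pairs if a in S1_NUCLEAR_SIDE)
        n_and = labels.count(FinalLabel.NUCLEAR_S1_AND_S2)
        n_extra = labels.count(FinalLabel.NUCLEAR_S1_EXTRA)
        assert n_and + n_extra == n_nuclear_side
        for (a, b), lab in zip(pairs, labels):
            if lab is not FinalLabel.NON_NUCLEAR:
                assert a in S1_NUCLEAR_SIDE
            if lab is FinalLabel.NUCLEAR_S1_AND_S2:
                assert b in S2_NUCLEAR_SIDE


class TestPercent:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (47, 1169, 4.0),
            (17, 1169, 1.5),
            (143, 4139, 3.5),
            (62, 4139, 1.5),
            (31, 4139, 0.7),
            (0, 10, 0.0),
            (1, 800, 0.1),  # 0.125 rounds half-up to 0.1
            (1, 16, 6.3),  # 6.25 rounds half-up to 6.3, not banker's 6.2
        ],
    )
    def test_printed_style_rounding(self, count, total, expected):
        assert percent_one_decimal(count, total) == expected

    @given(st.integers(0, 10**6), st.integers(1, 10**6))
    def test_half_up_property(self, k, n):
        k = min(k, n)
        from decimal import ROUND_HALF_UP, Decimal

        want = float(
            (Decimal(k) * 100 / Decimal(n)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        assert percent_one_decimal(k, n) == want


def _calls(spec):
    out = []
    i = 0
    for (s1, s2), k in spec.items():
        for _ in range(k):
            out.append(ConsensusCall(f"P{i}", s1, s2, merge_s1_s2(s1, s2)))
            i += 1
    return out


class TestSummaries:
    def test_counts_and_percentages(self):
        calls = _calls(
            {
                (S1Category.NUCLEAR, S2Category.NUCLEAR): 47,
                (S1Category.NON_CLASSIFIED, S2Category.NON_NUCLEAR): 1122,
            }
        )
        df = summarize_categories(calls, by="s2").set_index("category")
        assert df.loc["NUCLEAR", "id_count"] == 47
        assert df.loc["NUCLEAR", "id_percent"] == 4.0
        assert df.loc["TOTAL", "id_count"] == 1169

    def test_nsaf_shares_sum_to_one(self):
        calls = _calls(
            {
                (S1Category.NUCLEAR, S2Category.NUCLEAR): 3,
                (S1Category.CYTOSOLIC, S2Category.NON_NUCLEAR): 7,
            }
        )
        nsaf = pd.Series({c.protein_id: 0.1 for c in calls})
        df = summarize_categories(calls, nsaf=nsaf, by="s2")
        body = df[df.category != "TOTAL"]
        assert body.nsaf_share.sum() == pytest.approx(1.0, abs=1e-9)
        assert body.set_index("category").loc["NUCLEAR", "nsaf_share"] == pytest.approx(0.3)

    def test_empty_calls_error(self):
        with pytest.raises(ValueError):
            summarize_categories([], by="s2")


class TestKeywordCensus:
    NAMES = {
        "P1": "Histone H3.1",
        "P2": "kinesin-like protein",
        "P3": "Uncharacterized protein",
        "P4": "histone chaperone",
    }

    def test_case_insensitive_substring(self):
        df = keyword_census(self.NAMES, ["Histon", "Kinesin"]).set_index("search_string")
        assert df.loc["Histon", "total"] == 2
        assert df.loc["Kinesin", "total"] == 1

    def test_matched_vs_novel_split(self):
        df = keyword_census(
            self.NAMES, ["Histon"], reference_ids={"P1"}
        ).set_index("search_string")
        assert df.loc["Histon", "matched"] == 1
        assert df.loc["Histon", "novel"] == 1

    def test_no_reference_all_novel(self):
        df = keyword_census(self.NAMES, ["Histon"]).set_index("search_string")
        assert df.loc["Histon", "matched"] == 0
        assert df.loc["Histon", "novel"] == 2

    def test_protein_may_count_under_multiple_strings(self):
        df = keyword_census({"P1": "Histone chromatin factor"}, ["Histon", "Chromatin"])
        assert df.total.tolist() == [1, 1]

    def test_empty_strings_rejected(self):
        with pytest.raises(ValueError):
            keyword_census(self.NAMES, [])
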