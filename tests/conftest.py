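import dendropy
import pytest

from speclock.records import ClineRecord, InferenceMethod, LineagePair, MarkerGenome


def make_record(
    record_id="r1",
    pair_id="p1",
    transect_id="p1_t0",
    width_km=20.0,
    n_markers=1,
    marker_genome=MarkerGenome.NUCLEAR,
    inference_method=InferenceMethod.SINGLE,
    p_min=0.0,
    p_max=1.0,
    survey_label="",
):
    return ClineRecord(
        record_id=record_id,
        pair_id=pair_id,
        transect_id=transect_id,
        width_km=width_km,
        n_markers=n_markers,
        marker_genome=marker_genome,
        inference_method=inference_method,
        p_min=p_min,
        p_max=p_max,
        survey_label=survey_label,
    )


def make_pair(pair_id="p1", group="Lissamphibia", t_ma=2.0, dispersal="C"):
    return LineagePair(
        pair_id=pair_id,
        taxon_a=f"{pair_id}_a",
        taxon_b=f"{pair_id}_b",
        group=group,
        divergence_time_ma=t_ma,
        dispersal_category=dispersal,
    )


@pytest.fixture
def three_tip_tree():
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


#: Hand-built ultrametric trees with <= 12 tips exercising cherries,
#: ladders, polytomies and deep/shallow mixtures.
FIXTURE_NEWICKS = [
    "(A:1,B:1);",
    "((A:1,B:1):1,C:2);",
    "((A:2,B:2):3,(C:4,D:4):1);",
    "(((A:1,B:1):1,C:2):2,(D:3,E:3):1);",
    "((A:1,B:1):4,((C:2,D:2):2,(E:3,F:3):1):1);",
    "(A:5,B:5,C:5,D:5);",  # polytomy
    "((((A:0.5,B:0.5):0.5,C:1):1,(D:1.5,E:1.5):0.5):3,((F:2,G:2):2,(H:1,I:1):3):1);",
    "(((A:1,B:1):1,(C:1.5,D:1.5):0.5):8,(((E:3,F:3):3,(G:4,H:4):2):2,"
    "((I:2,J:2):5,(K:6,L:6):1):1):2);",
]
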