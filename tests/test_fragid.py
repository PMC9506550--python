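import numpy as np
import pytest

from brachymet import fragid
from brachymet.fragid import (
    MalformedTreeError, Scan, SpectrumTree, classify_amide,
    classify_flavonoid_glycoside, classify_hqa, classify_proanthocyanidin,
    classify_threonate_ester, extract_losses, identify, parse_msn_string,
    spectrum_trees,
)


def tree(msn, precursor, polarity="negative", resolution="low"):
    return parse_msn_string(msn, precursor, polarity, resolution)


def test_parse_msn_string_structure():
    t = tree("MS2:425*,407,289;MS3:245,205;MS4(205):177", 593.13)
    assert [s.level for s in t.scans] == [2, 3, 4]
    assert t.scans[0].base_mzs == (425.0,)
    assert t.scans[1].parent_mz == 425.0      # isolated = starred MS2 peak
    assert t.scans[2].parent_mz == 205.0      # explicit isolation parent
    # no star: the first peak is promoted to base with intensity 1
    assert t.scans[1].peaks[0] == (245.0, 1.0)
    assert t.scans[1].starred == ()


def test_malformed_tree_rejected():
    with pytest.raises(MalformedTreeError):
        SpectrumTree(300.0, "negative",
                     (Scan(2, 300.0, ((350.0, 1.0),), (350.0,)),))
    with pytest.raises(ValueError):
        SpectrumTree(300.0, "sideways", ())


def test_extract_losses_threonate_example():
    t = tree("MS2:193.050*,149.060", 311.077)
    losses = {round(l.loss, 3) for l in extract_losses(t)}
    assert 118.027 in losses                   # dehydrated threonate residue
    t0 = tree("MS2:311.077", 311.077)
    assert extract_losses(t0)[0].loss == pytest.approx(0.0)


def test_extract_losses_pairwise_oracle():
    rng = np.random.default_rng(20)
    prec = 600.0
    peaks = sorted(rng.uniform(100, 590, 6), reverse=True)
    t = tree("MS2:" + ",".join(f"{p:.3f}" for p in peaks), prec)
    got = {(l.parent_mz, round(l.loss, 3)) for l in extract_losses(t)}
    expect = {(prec, round(prec - p, 3)) for p in peaks}
    assert got == expect


@pytest.mark.parametrize("msn,precursor,expect_rule", [
    ("MS2:193,173*;MS3:109,93", 367.103, "hqa-4-feruloyl"),
    ("MS2:323,193*,173,135;MS3:149,135", 367.1028, "hqa-5-feruloyl"),
    ("MS2:353,179,173*", 353.067, "hqa-4-caffeoyl"),
])
def test_classify_hqa_regiochemistry(msn, precursor, expect_rule):
    m = classify_hqa(tree(msn, precursor))
    assert m is not None and m.rule_id == expect_rule
    assert m.class_assigned == "hydroxycinnamate-quinate"
    assert m.confidence == "diagnostic"


def test_classify_hqa_gates():
    assert classify_hqa(tree("MS2:173*", 500.0)) is None          # mass gate
    assert classify_hqa(tree("MS2:173*", 367.103, "positive")) is None


def test_classify_threonate_ester():
    m = classify_threonate_ester(tree("MS2:311,193*,149,135;MS3:135,119", 311.07697))
    assert m is not None and m.class_assigned == "hydroxycinnamate-threonate"
    assert "feruloylthreonic acid" in m.tags
    assert m.confidence == "diagnostic"
    # caffeoyl ester with the high-resolution twin ions at nominal 135
    m2 = classify_threonate_ester(
        tree("MS2:179,135.0288*,135.0444;MS3:117,89", 297.0611))
    assert m2 is not None and "caffeoylthreonic acid" in m2.tags
    # same nominal precursor, different exact mass: the gate must refuse
    assert classify_threonate_ester(tree("MS2:179,135*,117", 297.07752)) is None
    assert classify_threonate_ester(tree("MS2:100", 400.0)) is None


def test_classify_amide():
    m = classify_amide(tree("MS2:260*,217,147,114;MS3:217,98", 277.16547, "positive"))
    assert m is not None and m.class_assigned == "amide"
    assert "agmatine conjugate" in m.tags and "coumaroyl acyl" in m.tags
    m2 = classify_amide(tree("MS2:248,177*,144", 265.15424, "positive"))
    assert "putrescine conjugate" in m2.tags and "feruloyl acyl" in m2.tags
    assert classify_amide(tree("MS2:233,119", 277.165, "negative")) is None
    assert classify_amide(tree("MS2:657,641,479", 787.23, "positive")) is None


def test_classify_flavonoid_spec_examples():
    # 6''-O-hexosyl C-hexoside: base [M-90-H]-, one clean hexose loss, Agly+42
    m = classify_flavonoid_glycoside(
        tree("MS2:575,533,503*,473,431,311;MS3:413,383,311", 593.15198))
    assert m.class_assigned == "flavone-O,C-glycoside"
    assert m.aglycone == "apigenin"
    assert "6''-O-glycoside" in m.tags
    # 7-O-glucosyl C-glycoside: [M-162]- then Agly+42/+72 series
    m = classify_flavonoid_glycoside(
        tree("MS2:593,503,473,431,311*,297,283;MS3:311,283", 593.1506))
    assert m.class_assigned == "flavone-O,C-glycoside"
    assert "7-O-glycoside" in m.tags
    # di-C-glycoside: [Agly+84-H]- / [Agly+114-H]- main ions, no O loss
    m = classify_flavonoid_glycoside(
        tree("MS2:575,503,473,413,383*,353", 593.1505))
    assert m.class_assigned == "di-C-glycoside"
    # pure O-glycoside chain down to the aglycone anion
    m = classify_flavonoid_glycoside(tree("MS2:463,301", 625.14292))
    assert m.class_assigned == "flavone-O-glycoside"
    assert m.aglycone == "quercetin"
    # mono C-glycoside: cross-ring losses and Agly+42/+72 only
    m = classify_flavonoid_glycoside(
        tree("MS2:341,311*,283;MS3:283,237,117", 431.0994))
    assert m.class_assigned == "flavone-C-glycoside"


def test_interglycosidic_bond_tags():
    # [M+H-164]+ (full deoxyhexose) marks a (1->2) bond
    m = classify_flavonoid_glycoside(
        tree("MS2:493*,475,331;MS3:331,315", 639.19, "positive"))
    assert any("(1->2)" in t for t in m.tags)
    # -146 and -308 pattern without -164 marks (1->6)
    m = classify_flavonoid_glycoside(
        tree("MS2:493,331*;MS3:315,269", 639.185, "positive"))
    assert any("(1->6)" in t for t in m.tags)


def test_classify_proanthocyanidin():
    # RDA-gallocatechin loss plus quinone-methide (epi)catechin ion
    m = classify_proanthocyanidin(
        tree("MS2:574,467,425*,407,289;MS3:245,205,177", 593.13153))
    assert m is not None and m.confidence == "diagnostic"
    assert "B-type dimer" in m.tags
    assert any("catechin" in t for t in m.tags)
    # procyanidin B dimer via the 289 monomer ion
    m = classify_proanthocyanidin(tree("MS2:577,407*,289;MS3:289,143", 577.13679))
    assert m.confidence == "diagnostic" and "B-type dimer" in m.tags
    # A- vs B-type split on the 2 Da precursor parity
    a = classify_proanthocyanidin(tree("MS2:589*,333,203", 607.11102))
    b = classify_proanthocyanidin(tree("MS2:595,483*,305", 609.12659))
    assert "A-type dimer" in a.tags and "B-type dimer" in b.tags
    assert classify_proanthocyanidin(tree("MS2:289", 700.0)) is None


def test_rule_independence_and_intensity_permutation(library):
    rec = next(r for r in library if r.compound_id == "c15")
    t = spectrum_trees(rec)[0]
    call = identify([t], library=library)
    # permuting intensities within a scan (base markers travel) is a no-op
    scans = tuple(Scan(s.level, s.parent_mz, tuple(reversed(s.peaks)),
                       s.base_mzs, s.starred) for s in t.scans)
    t2 = SpectrumTree(t.precursor_mz, t.polarity, scans, t.resolution)
    call2 = identify([t2], library=library)
    assert call.best_class == call2.best_class
    assert call.msi_level == call2.msi_level


def test_tolerance_layering(library):
    # every rule firing at high-res tolerance also fires at the low-res one
    rules = (classify_hqa, classify_threonate_ester, classify_amide,
             classify_flavonoid_glycoside, classify_proanthocyanidin)
    for rec in library:
        for t in spectrum_trees(rec):
            for rule in rules:
                if rule(t, tol=fragid.TOL_HIGH) is not None:
                    assert rule(t, tol=fragid.TOL_LOW) is not None, (
                        rec.compound_id, rule.__name__)


def test_identify_empty_tree_class_unassigned(library):
    t = SpectrumTree(593.15155, "negative", ())
    call = identify([t], library=library)
    assert call.best_class is None
    assert call.msi_level == 3
    assert call.candidate_names            # precursor-mass candidates remain


def test_identify_conformer_annotation(library):
    # the two feruloyl-N-putrescine isomers share formula, class and spectrum
    rec = next(r for r in library if r.compound_id == "c23")
    call = identify(spectrum_trees(rec), library=library)
    assert call.best_class == "amide"
    assert any("conformer" in t for t in call.tags)


def test_std_rows_reach_level_1(library):
    for rec in library:
        if rec.std:
            call = identify(spectrum_trees(rec), library=library)
            assert call.msi_level == 1, rec.compound_id
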