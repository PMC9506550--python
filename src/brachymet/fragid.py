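"""Rule-based structural classification of MS/MS - MS^n spectrum trees.

The engine mirrors how phenylpropanoid and flavonoid chemistry is read
off fragmentation spectra by hand:

* hydroxycinnamoyl-quinic acids (HQA): 4-acyl isomers give a base
  product ion at nominal m/z 173 (quinate), 5-acyl isomers give the
  hydroxycinnamate anion (179 caffeate / 163 coumarate / 193 ferulate);
* hydroxycinnamoyl threonate esters: neutral loss of the dehydrated
  threonate residue (118.03 Da) with the complementary acid anion;
* hydroxycinnamic acid amides: losses of putrescine (88), agmatine
  (130) or spermidine (145) with acyl cations at 147/163/177;
* flavonoid glycosides: clean losses of dehydrated sugars (162 hexose,
  146 deoxyhexose, 132 pentose, 308 hexosyl-deoxyhexose) mark
  O-glycosides; aglycone+41/+71 product ions and cross-ring 90/120
  losses mark C-glycosides; aglycone+83/+113 ions mark di-C-glycosides;
  combinations mark O,C-glycosides, with 7-O / 2''-O / 6''-O position
  tags and (1->2)/(1->6) interglycosidic-bond tags from the
  positive-mode loss pattern;
* flavan-3-ols / proanthocyanidins: quinone-methide cleavage monomer
  ions (289 (epi)catechin, 305 (epi)gallocatechin), retro-Diels-Alder
  losses (152/168), heterocyclic ring fission (126), and galloyl /
  hydroxybenzoyl losses (152.011/120.021), with A- vs B-type read from
  the 2-Da precursor-mass parity;
* free amino acids: NH3 (17) or HCOOH+ (46) losses from a precursor
  matching a proteinogenic amino-acid [M+H]+.

Identification calls intersect the fired classes with library precursor
matches and assign MSI confidence levels: 1 for a standard-linked
library match of precursor, fragmentation (and retention time when both
sides carry one), 2 for a spectral library match, 3 for class-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .chemmass import PROTON_MASS, ion_mz, ppm_error
from .library import CompoundRecord, load_compound_library

__all__ = [
    "Scan", "SpectrumTree", "Evidence", "RuleMatch", "IdentificationCall",
    "MalformedTreeError", "parse_msn_string", "spectrum_trees",
    "extract_losses", "classify_hqa", "classify_threonate_ester",
    "classify_amide", "classify_flavonoid_glycoside",
    "classify_proanthocyanidin", "classify_amino_acid",
    "identify", "replay_fixtures",
]

TOL_LOW = 0.5     # Da, ion-trap nominal masses
TOL_HIGH = 0.005  # Da, orbitrap product ions
LOSS_TOL = 0.6    # Da window for nominal neutral-loss matching
PRECURSOR_GATE_LOW = 0.3   # Da, library precursor gate at low resolution
PRECURSOR_GATE_PPM = 5.0   # ppm, library precursor gate at high resolution

AGLYCONES = {           # neutral nominal masses of the flavone/flavonol cores
    "apigenin": 270, "luteolin": 286, "chrysoeriol": 300,
    "tricin": 330, "quercetin": 302, "isorhamnetin": 316,
}
SUGAR_RESIDUES = {"hexose": 162, "deoxyhexose": 146, "pentose": 132}
ACYL_RESIDUES = {"malonyl": 86, "sinapoyl": 206}

# nominal [M-H]- masses of flavan-3-ol monomers, their aroyl esters and
# B-/A-type oligomers ((epi)catechin 290 / (epi)gallocatechin 306 units)
_PA_UNITS = (290, 306)
_PA_PRECURSORS = {289, 305, 425, 441, 457, 473}
for _a in _PA_UNITS:
    for _b in _PA_UNITS:
        _PA_PRECURSORS.add(_a + _b - 3)      # B-type dimer anion
        _PA_PRECURSORS.add(_a + _b - 5)      # A-type dimer anion
        for _c in _PA_UNITS:
            _PA_PRECURSORS.add(_a + _b + _c - 5)   # B-type trimer
            _PA_PRECURSORS.add(_a + _b + _c - 7)   # A-type trimer
_PA_QM_MONOMERS = {287: "(epi)catechin (extension)", 289: "(epi)catechin",
                   303: "(epi)gallocatechin (extension)", 305: "(epi)gallocatechin"}

_ACIDS_NEG = {"caffeoyl": 179, "coumaroyl": 163, "feruloyl": 193}
_ACIDS_POS = {"caffeoyl": 163, "coumaroyl": 147, "feruloyl": 177}
_HQA_PRECURSORS = {353: "caffeoyl", 337: "coumaroyl", 367: "feruloyl"}
# formula-derived [M-H]- of the three hydroxycinnamoyl threonates
_THREONATE_PRECURSORS = {
    "caffeoyl": ion_mz("C13H14O8", "[M-H]-"),
    "coumaroyl": ion_mz("C13H14O7", "[M-H]-"),
    "feruloyl": ion_mz("C14H16O8", "[M-H]-"),
}
_AMINES = {"putrescine": 88, "agmatine": 130, "spermidine": 145}
_AMINO_ACIDS_POS = {  # [M+H]+ of the free amino acids seen in these extracts
    "leucine/isoleucine": 132.1019, "valine": 118.0863,
    "phenylalanine": 166.0863, "tyrosine": 182.0812, "tryptophan": 205.0972,
}


class MalformedTreeError(ValueError):
    pass


def _near(a: float, b: float, tol: float) -> bool:
    return abs(a - b) <= tol


@dataclass(frozen=True)
class Scan:
    level: int
    parent_mz: float
    peaks: tuple            # ((mz, relative_intensity), ...) base peak = 1.0
    base_mzs: tuple         # m/z values marked as main/base peaks
    starred: tuple = ()     # subset of base_mzs explicitly marked in the source

    def mzs(self):
        return tuple(p[0] for p in self.peaks)


@dataclass(frozen=True)
class SpectrumTree:
    precursor_mz: float
    polarity: str
    scans: tuple
    resolution: str = "low"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.resolution not in ("low", "high"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        for scan in self.scans:
            for mz, inten in scan.peaks:
                if mz >= scan.parent_mz + 0.5:
                    raise MalformedTreeError(
                        f"MS{scan.level} product {mz} heavier than parent {scan.parent_mz}")
                if not 0 <= inten <= 1:
                    raise MalformedTreeError("intensities must be normalized to [0, 1]")

    def all_products(self):
        return tuple(mz for scan in self.scans for mz in scan.mzs())

    def scan(self, level: int) -> Optional[Scan]:
        for s in self.scans:
            if s.level == level:
                return s
        return None

    @property
    def tol(self) -> float:
        return TOL_LOW if self.resolution == "low" else TOL_HIGH


def parse_msn_string(text: str, precursor_mz: float, polarity: str,
                     resolution: str = "low") -> SpectrumTree:
    """Parse the compact pathway notation into a SpectrumTree.

    ``'MS2:425*,407,289;MS3:245,205'`` - scans separated by ';', peaks
    by ',', '*' marks the main (base/isolated) peaks, and an explicit
    isolation parent may be given as ``MS3(483):...``.  Without an
    explicit parent the first starred peak (else the first peak) of the
    previous scan is taken as isolated.
    """
    scans = []
    prev: Optional[Scan] = None
    for part in filter(None, (p.strip() for p in text.split(";"))):
        head, _, body = part.partition(":")
        if "(" in head:
            level_s, parent_s = head[:-1].split("(")
            parent = float(parent_s)
        else:
            level_s = head
            if prev is None:
                parent = precursor_mz
            else:
                parent = prev.base_mzs[0] if prev.base_mzs else prev.peaks[0][0]
        level = int(level_s.replace("MS", ""))
        peaks, bases, starred = [], [], []
        for tok in filter(None, (t.strip() for t in body.split(","))):
            star = tok.endswith("*")
            mz = float(tok.rstrip("*"))
            peaks.append((mz, 1.0 if star else 0.5))
            if star:
                bases.append(mz)
                starred.append(mz)
        if not bases and peaks:
            peaks[0] = (peaks[0][0], 1.0)
            bases = [peaks[0][0]]
        scan = Scan(level, parent, tuple(peaks), tuple(bases), tuple(starred))
        scans.append(scan)
        prev = scan
    if not scans and text.strip():
        raise MalformedTreeError(f"cannot parse spectrum string {text!r}")
    return SpectrumTree(precursor_mz, polarity, tuple(scans), resolution)


def spectrum_trees(record: CompoundRecord) -> list[SpectrumTree]:
    """Both polarity trees transcribed for a library record."""
    neutral = record.measured_mz - PROTON_MASS * record.ion_type.charge_sign
    trees = []
    if record.msn_negative:
        trees.append(parse_msn_string(record.msn_negative,
                                      neutral - PROTON_MASS, "negative"))
    if record.msn_positive:
        trees.append(parse_msn_string(record.msn_positive,
                                      neutral + PROTON_MASS, "positive"))
    return trees


@dataclass(frozen=True)
class Loss:
    level: int
    parent_mz: float
    product_mz: float
    loss: float
    is_base: bool


def extract_losses(tree: SpectrumTree) -> list[Loss]:
    """All parent-to-product mass differences, per scan."""
    out = []
    for scan in tree.scans:
        for mz, _ in scan.peaks:
            out.append(Loss(scan.level, scan.parent_mz, mz,
                            scan.parent_mz - mz, mz in scan.base_mzs))
    return out


@dataclass(frozen=True)
class Evidence:
    kind: str        # 'loss' or 'product'
    level: int
    observed: float
    matched: str     # dictionary entry / expected-ion description
    error: float     # observed minus expected, Da


@dataclass(frozen=True)
class RuleMatch:
    rule_id: str
    class_assigned: str
    evidence: tuple
    confidence: str                  # 'diagnostic' | 'supporting'
    tags: tuple = ()
    aglycone: Optional[str] = None
    sugar_inventory: Optional[dict] = None


def _decompose_sugars(delta: float, max_sugars: int = 4, tol: float = 2.0,
                      allowed_acyls: Sequence[str] = ()) -> Optional[dict]:
    """Express a nominal mass difference as 1..max_sugars sugar residues
    plus at most one acyl residue; None when impossible.  An acyl
    residue is only considered when listed in ``allowed_acyls`` (i.e.
    when the corresponding acyl loss was actually observed)."""
    best = None
    acyl_options = [("", 0)] + [(n, ACYL_RESIDUES[n]) for n in allowed_acyls]
    for nh in range(max_sugars + 1):
        for nd in range(max_sugars + 1 - nh):
            for npent in range(max_sugars + 1 - nh - nd):
                total = nh + nd + npent
                if not 1 <= total <= max_sugars:
                    continue
                base = 162 * nh + 146 * nd + 132 * npent
                for acyl_name, acyl in acyl_options:
                    err = abs(delta - base - acyl)
                    if err <= tol and (best is None or err < best[0]):
                        inv = {"hexose": nh, "deoxyhexose": nd, "pentose": npent}
                        if acyl_name:
                            inv[acyl_name] = 1
                        best = (err, inv)
    return best[1] if best else None


def _observed_acyls(tree: "SpectrumTree") -> tuple:
    """Acyl residues whose neutral loss appears anywhere in the tree."""
    losses = [l.loss for l in extract_losses(tree)]
    out = []
    if any(_near(l, 86, LOSS_TOL) for l in losses):
        out.append("malonyl")
    if any(any(_near(l, v, LOSS_TOL) for v in (206, 224, 368)) for l in losses):
        out.append("sinapoyl")
    return tuple(out)


def _o_glycoside_context(tree: "SpectrumTree") -> bool:
    """True when the precursor scan shows O-glycoside behaviour: a clean
    dehydrated-sugar loss, or a base peak at [M-(sugar+H2O)]."""
    ms2 = tree.scan(2)
    if ms2 is None:
        return False
    for mz in ms2.mzs():
        loss = ms2.parent_mz - mz
        if any(_near(loss, v, LOSS_TOL) for v in (162, 146, 132, 308)):
            return True
        if mz in ms2.base_mzs and _near(loss, 180, LOSS_TOL):
            return True
    return False


# ---------------------------------------------------------------------------
# individual classifiers (independent pattern matchers)
# ---------------------------------------------------------------------------

def classify_hqa(tree: SpectrumTree, tol: float | None = None) -> Optional[RuleMatch]:
    """4- vs 5-acyl regiochemistry of hydroxycinnamoyl-quinic acids."""
    if tree.polarity != "negative":
        return None
    tol = tree.tol if tol is None else tol
    nominal = round(tree.precursor_mz)
    acid = _HQA_PRECURSORS.get(nominal)
    if acid is None:
        return None
    ms2 = tree.scan(2)
    if ms2 is None or not ms2.peaks:
        return None
    bases = ms2.base_mzs
    for b in bases:
        if _near(b, 173, max(tol, LOSS_TOL)):
            ev = (Evidence("product", 2, b, "quinate anion (4-acyl diagnostic)", b - 173),)
            return RuleMatch(f"hqa-4-{acid}", "hydroxycinnamate-quinate", ev,
                             "diagnostic", tags=(f"4-{acid}quinic acid",))
    acid_anion = _ACIDS_NEG[acid]
    for b in bases:
        if _near(b, acid_anion, max(tol, LOSS_TOL)):
            ev = (Evidence("product", 2, b, f"{acid[:-2]}ate anion (5-acyl diagnostic)",
                           b - acid_anion),)
            return RuleMatch(f"hqa-5-{acid}", "hydroxycinnamate-quinate", ev,
                             "diagnostic", tags=(f"5-{acid}quinic acid",))
    return RuleMatch(f"hqa-unassigned-{acid}", "hydroxycinnamate-quinate", (),
                     "supporting", tags=("unassigned-HQA regiochemistry",))


def classify_threonate_ester(tree: SpectrumTree,
                             tol: float | None = None) -> Optional[RuleMatch]:
    """Hydroxycinnamoyl threonate esters via the 118.03 Da threonate loss."""
    if tree.polarity != "negative":
        return None
    tol = tree.tol if tol is None else tol
    acid = None
    for name, theo in _THREONATE_PRECURSORS.items():
        if abs(ppm_error(tree.precursor_mz, theo)) <= 10.0:
            acid = name
    if acid is None:
        return None
    evidence, diagnostic = [], False
    for loss in extract_losses(tree):
        if _near(loss.loss, 118.027, max(tol, LOSS_TOL)):
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "threonate-H2O", loss.loss - 118.027))
            diagnostic = True
    acid_anion = _ACIDS_NEG[acid]
    for p in tree.all_products():
        if _near(p, acid_anion, max(tol, LOSS_TOL)):
            evidence.append(Evidence("product", 0, p,
                                     f"complementary {acid[:-2]}ate anion",
                                     p - acid_anion))
    # supporting in-source acyl fragments: [acyl-CO2]- and [acyl-C2O2]-
    for delta, label in ((44, "[acyl-CO2]-"), (72, "[acyl-C2O2]-")):
        for p in tree.all_products():
            if _near(p, acid_anion - delta, max(tol, LOSS_TOL)):
                evidence.append(Evidence("product", 0, p, label,
                                         p - (acid_anion - delta)))
    if not evidence:
        return None
    return RuleMatch(f"threonate-{acid}", "hydroxycinnamate-threonate",
                     tuple(evidence),
                     "diagnostic" if diagnostic else "supporting",
                     tags=(f"{acid}threonic acid",))


def classify_amide(tree: SpectrumTree, tol: float | None = None) -> Optional[RuleMatch]:
    """Hydroxycinnamic acid polyamine amides (positive mode)."""
    if tree.polarity != "positive" or tree.precursor_mz > 450:
        return None
    tol = tree.tol if tol is None else tol
    losses = extract_losses(tree)
    evidence, amine = [], None
    for name, nominal in _AMINES.items():
        for loss in losses:
            if _near(loss.loss, nominal, max(tol, LOSS_TOL)):
                evidence.append(Evidence("loss", loss.level, loss.loss,
                                         name, loss.loss - nominal))
                amine = amine or name
    for p in tree.all_products():   # protonated putrescine itself
        if _near(p, 89.1, max(tol, LOSS_TOL)):
            evidence.append(Evidence("product", 0, p, "putrescine [M+H]+", p - 89.1))
            amine = amine or "putrescine"
    if amine is None:
        return None
    acyl = None
    for name, cation in _ACIDS_POS.items():
        for p in tree.all_products():
            if _near(p, cation, max(tol, LOSS_TOL)):
                evidence.append(Evidence("product", 0, p,
                                         f"{name} acylium", p - cation))
                acyl = acyl or name
    for loss in losses:   # supporting NH3 loss
        if _near(loss.loss, 17, max(tol, LOSS_TOL)):
            evidence.append(Evidence("loss", loss.level, loss.loss, "ammonia",
                                     loss.loss - 17.027))
    tags = [f"{amine} conjugate"]
    if acyl:
        tags.append(f"{acyl} acyl")
    return RuleMatch(f"amide-{amine}", "amide", tuple(evidence), "diagnostic",
                     tags=tuple(tags))


def classify_amino_acid(tree: SpectrumTree,
                        tol: float | None = None) -> Optional[RuleMatch]:
    """Free proteinogenic amino acids: NH3 / HCOOH+CO-type losses from a
    matching [M+H]+ precursor."""
    if tree.polarity != "positive":
        return None
    tol = tree.tol if tol is None else tol
    name = None
    for aa, mh in _AMINO_ACIDS_POS.items():
        if abs(tree.precursor_mz - mh) <= 0.01 or abs(ppm_error(tree.precursor_mz, mh)) <= 10:
            name = aa
    if name is None:
        return None
    evidence = []
    for loss in extract_losses(tree):
        if _near(loss.loss, 17, max(tol, LOSS_TOL)):
            evidence.append(Evidence("loss", loss.level, loss.loss, "ammonia",
                                     loss.loss - 17.027))
        elif _near(loss.loss, 46, max(tol, LOSS_TOL)):
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "formic-acid (H2O+CO)", loss.loss - 46.005))
    if not evidence:
        return None
    return RuleMatch(f"amino-acid-{name}", "amino-acid", tuple(evidence),
                     "diagnostic", tags=(name,))


#: tie-break order for isobaric aglycone interpretations (field prevalence
#: in Poaceae extracts; earlier wins)
_AGLYCONE_PRIORITY = ("apigenin", "luteolin", "chrysoeriol", "tricin",
                      "quercetin", "isorhamnetin")


def _infer_aglycone(tree: SpectrumTree, tol: float):
    """Best-scoring aglycone candidate consistent with the precursor mass.

    A candidate must pass the composition gate (precursor minus aglycone
    decomposable into sugar/acyl residues) and show its bare aglycone
    ion (weight 3 in the precursor scan, 1.5 deeper, where it may be a
    coincidental secondary fragment) or aglycone+residue product ions:
    the C-glycoside +41/+71 series weighs 2 each, the 2''-O +23/+53
    series 1 each, a lone member of the di-C +83/+113 pair only 0.5 and
    the complete pair 2 (single members are commonly [M-sugar] ions of
    another aglycone); an explicitly marked base-peak signature adds 1.
    Low-resolution MS^n cannot always separate isobaric aglycone/sugar
    combinations (e.g. apigenin+2 hexoses vs chrysoeriol+hexose+
    pentose); exact ties are broken by prevalence.
    """
    charge = 1 if tree.polarity == "positive" else -1
    neutral_nominal = round(tree.precursor_mz) - charge
    products = tree.all_products()
    ms2 = tree.scan(2)
    ms2_products = ms2.mzs() if ms2 is not None else ()
    starred = {mz for scan in tree.scans for mz in scan.starred}
    ltol = max(tol, LOSS_TOL)
    acyls = _observed_acyls(tree)
    o_context = _o_glycoside_context(tree)
    best = None
    for prio, name in enumerate(_AGLYCONE_PRIORITY):
        M = AGLYCONES[name]
        inventory = _decompose_sugars(neutral_nominal - M, allowed_acyls=acyls)
        if inventory is None:
            continue
        agly_ion = M + charge
        score = 0.0
        anion_seen = any(_near(p, agly_ion, ltol) for p in products)
        if any(_near(p, agly_ion, ltol) for p in ms2_products):
            score += 3.0
        elif anion_seen:
            score += 1.5
        if tree.polarity == "negative":
            hits = {}
            for sig in (42, 72, 84, 114, 24, 54):
                hit = [p for p in products if _near(p, agly_ion + sig, ltol)]
                if hit:
                    hits[sig] = hit
            for sig in (42, 72):
                if sig in hits:
                    score += 2.0
            for sig in (24, 54):
                # the 2''-O dehydrated series is only meaningful in an
                # O-glycoside context; otherwise these are [M-sugar]-type
                # coincidences of another aglycone
                if sig in hits and o_context:
                    score += 1.0
                elif sig in hits:
                    del hits[sig]
            di = [s for s in (84, 114) if s in hits]
            score += 2.0 if len(di) == 2 else 0.5 * len(di)
            if any(p in starred for hit in hits.values() for p in hit):
                score += 1.0
        if score >= 1.0:
            key = (score, anion_seen, -prio)
            if best is None or key > best[0]:
                best = (key, name, M, inventory)
    if best is None:
        return None
    return best[1], best[2], best[3]


def classify_flavonoid_glycoside(tree: SpectrumTree,
                                 tol: float | None = None) -> Optional[RuleMatch]:
    """O-, C-, O,C- and di-C-glycosides of the flavone/flavonol aglycones."""
    tol = tree.tol if tol is None else tol
    inferred = _infer_aglycone(tree, tol)
    if inferred is None:
        return None
    aglycone, M, inventory = inferred
    charge = 1 if tree.polarity == "positive" else -1
    agly_ion = M + charge
    losses = extract_losses(tree)
    evidence, tags = [], []
    ltol = max(tol, LOSS_TOL)
    o_context = _o_glycoside_context(tree)
    # glycosidic evidence is read from the precursor (MS2) scan; sugar-mass
    # gaps in deeper scans are cross-ring completions of C-bound sugars
    ms2 = tree.scan(2)
    ms2_products = ms2.mzs() if ms2 else ()
    ms2_losses = [l for l in losses if l.level == 2]

    mono_c, di_c, two_prime = [], [], []
    if tree.polarity == "negative":
        for sig, bucket, label in ((42, mono_c, "[Agly+42-H]-"),
                                   (72, mono_c, "[Agly+72-H]-"),
                                   (84, di_c, "[Agly+84-H]-"),
                                   (114, di_c, "[Agly+114-H]-"),
                                   (24, two_prime, "[Agly+(42-18)-H]-"),
                                   (54, two_prime, "[Agly+(72-18)-H]-")):
            if bucket is two_prime and not o_context:
                continue
            for p in ms2_products:
                if _near(p, agly_ion + sig, ltol):
                    bucket.append(p)
                    evidence.append(Evidence("product", 2, p, label,
                                             p - (agly_ion + sig)))
    has_c = bool(mono_c or di_c or two_prime)

    def _is_c_sig(mz: float) -> bool:
        return any(_near(mz, agly_ion + sig, ltol)
                   for sig in (24, 42, 54, 72, 84, 114))

    o_losses = []
    o_loss_set = dict(SUGAR_RESIDUES)
    o_loss_set["hexosyl-deoxyhexose"] = 308
    if tree.polarity == "positive":
        o_loss_set["deoxyhexose (full)"] = 164
    for loss in ms2_losses:
        for label, nominal in o_loss_set.items():
            if _near(loss.loss, nominal, ltol):
                if _is_c_sig(loss.product_mz):
                    continue   # terminates on a C-sugar fragment ion
                if _near(loss.product_mz, agly_ion, ltol) and has_c:
                    continue   # C-glycosides can expose a bare aglycone ion
                o_losses.append((label, loss))
                evidence.append(Evidence("loss", loss.level, loss.loss,
                                         f"dehydrated {label}", loss.loss - nominal))
        # [M-(sugar+H2O)] as the scan base marks a 2''-O-glycosylated C-sugar
        if (_near(loss.loss, 180, ltol) and loss.is_base
                and not _is_c_sig(loss.product_mz)):
            o_losses.append(("hexose (full)", loss))
            tags.append("2''-O-glycoside")
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "hexose+H2O (2''-O signature)", loss.loss - 180.063))
    if not has_c and ms2 is not None:
        # within-scan gaps ending at the aglycone ion (sequential losses)
        for lo in ms2_products:
            if not _near(lo, agly_ion, ltol):
                continue
            for hi in ms2_products:
                for label, nominal in o_loss_set.items():
                    if hi > lo and _near(hi - lo, nominal, ltol):
                        o_losses.append((label, Loss(2, hi, lo, hi - lo, False)))
                        evidence.append(Evidence("loss", 2, hi - lo,
                                                 f"dehydrated {label} (sequential)",
                                                 hi - lo - nominal))
    has_o = bool(o_losses) or bool(two_prime)

    if has_c and has_o:
        cls = "flavone-O,C-glycoside"
    elif di_c:
        cls = "di-C-glycoside"
    elif mono_c:
        cls = "flavone-C-glycoside"
    elif has_o:
        cls = "flavone-O-glycoside"
    else:
        # cross-ring losses alone (90/120 hexose, 74/104 pentose) are
        # supporting C-attachment evidence, not class-defining
        return None

    if two_prime and "2''-O-glycoside" not in tags:
        tags.append("2''-O-glycoside")
    if cls == "flavone-O,C-glycoside":
        ms2 = tree.scan(2)
        if ms2 is not None:
            for b in ms2.base_mzs:
                if (_near(ms2.parent_mz - b, 90, ltol)
                        or _near(ms2.parent_mz - b, 102, ltol)):
                    tags.append("6''-O-glycoside")
        if (any(lbl == "hexose" for lbl, _ in o_losses)
                and not any(t.startswith(("2''", "6''")) for t in tags)):
            tags.append("7-O-glycoside")
    if tree.polarity == "positive" and cls == "flavone-O-glycoside":
        full_deoxy = any(lbl.startswith("deoxyhexose (full)") for lbl, _ in o_losses)
        if full_deoxy:
            tags.append("deoxyhexosyl(1->2) interglycosidic bond")
        elif (any(lbl == "deoxyhexose" for lbl, _ in o_losses)
              and any(lbl in ("hexose", "hexosyl-deoxyhexose") for lbl, _ in o_losses)):
            tags.append("deoxyhexosyl(1->6) interglycosidic bond")
    if cls in ("flavone-O-glycoside", "flavone-O,C-glycoside"):
        acyl_losses = ms2_losses
    else:
        acyl_losses = []
    for loss in acyl_losses:   # sinapoyl acylation (supplementary, low confidence)
        if any(_near(loss.loss, v, ltol) for v in (206, 224, 368)):
            tags.append("acylated (sinapoyl) - low confidence")
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "sinapoyl-related", 0.0))
            break
    observed = {"hexose": 0, "deoxyhexose": 0, "pentose": 0}
    for lbl, _ in o_losses:
        if lbl == "hexosyl-deoxyhexose":
            observed["hexose"] += 1
            observed["deoxyhexose"] += 1
        else:
            observed[lbl.split(" ")[0]] = observed.get(lbl.split(" ")[0], 0) + 1
    return RuleMatch(f"flavonoid-{cls}", cls, tuple(evidence), "diagnostic",
                     tags=tuple(dict.fromkeys(tags)), aglycone=aglycone,
                     sugar_inventory={"planted": inventory, "observed": observed})


def classify_proanthocyanidin(tree: SpectrumTree,
                              tol: float | None = None) -> Optional[RuleMatch]:
    """Flavan-3-ol monomers/oligomers via QM, RDA and HRF fragmentations."""
    if tree.polarity != "negative":
        return None
    tol = tree.tol if tol is None else tol
    nominal = round(tree.precursor_mz)
    if min(abs(nominal - p) for p in _PA_PRECURSORS) > 1:
        return None
    if not tree.all_products():
        return None   # a bare precursor mass is no evidence
    ltol = max(tol, LOSS_TOL)
    evidence, monomers, tags = [], [], []
    for p in tree.all_products():
        for qm, label in _PA_QM_MONOMERS.items():
            if _near(p, qm, ltol):
                evidence.append(Evidence("product", 0, p,
                                         f"QM cleavage: {label}", p - qm))
                monomers.append(label)
    rda = hrf = False
    for loss in extract_losses(tree):
        if _near(loss.loss, 152, ltol):
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "RDA-catechin / gallate-related", loss.loss - 152.047))
            rda = True
        elif _near(loss.loss, 168, ltol):
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "RDA-gallocatechin", loss.loss - 168.042))
            rda = True
        elif _near(loss.loss, 126, ltol):
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "HRF", loss.loss - 126.032))
            hrf = True
        elif _near(loss.loss, 120, ltol):
            evidence.append(Evidence("loss", loss.level, loss.loss,
                                     "hydroxybenzoate-related", loss.loss - 120.021))
    diagnostic = bool(monomers) or (rda and hrf)
    if nominal in {_a + _b - 5 for _a in _PA_UNITS for _b in _PA_UNITS}:
        tags.append("A-type dimer")
    elif nominal in {_a + _b - 3 for _a in _PA_UNITS for _b in _PA_UNITS}:
        tags.append("B-type dimer")
    elif nominal >= 860:
        tags.append("trimer")
    if monomers:
        tags.append("monomers: " + ", ".join(sorted(set(monomers))))
    return RuleMatch("proanthocyanidin", "proanthocyanidin", tuple(evidence),
                     "diagnostic" if diagnostic else "supporting",
                     tags=tuple(tags))


CLASSIFIERS = (classify_hqa, classify_threonate_ester, classify_amide,
               classify_amino_acid, classify_flavonoid_glycoside,
               classify_proanthocyanidin)

_FLAVONOID_FAMILY = {"flavone-O-glycoside", "flavone-C-glycoside",
                     "flavone-O,C-glycoside", "di-C-glycoside"}


@dataclass(frozen=True)
class IdentificationCall:
    best_class: Optional[str]
    candidate_names: tuple
    msi_level: int
    rationale: tuple
    matches: tuple = ()
    ambiguous: bool = False
    tags: tuple = ()


def _merge_classes(classes: list[str]):
    """Combine per-tree class calls; flavonoid family members merge."""
    uniq = list(dict.fromkeys(classes))
    if len(uniq) <= 1:
        return (uniq[0] if uniq else None), False
    if set(uniq) <= _FLAVONOID_FAMILY:
        if "flavone-O,C-glycoside" in uniq:
            return "flavone-O,C-glycoside", False
        has_c = any(c in ("flavone-C-glycoside", "di-C-glycoside") for c in uniq)
        has_o = "flavone-O-glycoside" in uniq
        if has_c and has_o:
            return "flavone-O,C-glycoside", False
        if "di-C-glycoside" in uniq:
            return "di-C-glycoside", False
        return uniq[0], False
    return None, True


def _spectral_overlap(tree: SpectrumTree, record: CompoundRecord) -> float:
    """Fraction of the record's recorded product ions found in the tree."""
    text = record.msn_negative if tree.polarity == "negative" else record.msn_positive
    if not text:
        return 0.0
    neutral = record.measured_mz - PROTON_MASS * record.ion_type.charge_sign
    prec = neutral + PROTON_MASS * (1 if tree.polarity == "positive" else -1)
    ref = parse_msn_string(text, prec, tree.polarity)
    ref_peaks = ref.all_products()
    if not ref_peaks:
        return 0.0
    obs = tree.all_products()
    hit = sum(1 for rp in ref_peaks if any(_near(o, rp, LOSS_TOL) for o in obs))
    return hit / len(ref_peaks)


def _precursor_candidates(tree: SpectrumTree, library, tol_ppm: float):
    hits = []
    for rec in library:
        if rec.ion_type.polarity == tree.polarity:
            theo = rec.measured_mz
        else:
            neutral = rec.measured_mz - PROTON_MASS * rec.ion_type.charge_sign
            theo = neutral + PROTON_MASS * (1 if tree.polarity == "positive" else -1)
        if tree.resolution == "high":
            ok = abs(ppm_error(tree.precursor_mz, theo)) <= tol_ppm
        else:
            ok = abs(tree.precursor_mz - theo) <= PRECURSOR_GATE_LOW
        if ok:
            hits.append((rec, abs(tree.precursor_mz - theo)))
    return hits


def identify(trees, library=None, rt: float | None = None,
             tol_ppm: float = PRECURSOR_GATE_PPM) -> IdentificationCall:
    """Run every classifier over one or more polarity trees of the same
    precursor, intersect with library precursor matches, and assign an
    MSI confidence level."""
    if isinstance(trees, SpectrumTree):
        trees = [trees]
    if library is None:
        library = load_compound_library()
    matches: list[RuleMatch] = []
    for tree in trees:
        for rule in CLASSIFIERS:
            m = rule(tree)
            if m is not None:
                matches.append(m)
    diagnostic = [m for m in matches if m.confidence == "diagnostic"]
    pool = diagnostic if diagnostic else matches
    best_class, ambiguous = _merge_classes([m.class_assigned for m in pool])
    tags = tuple(dict.fromkeys(t for m in matches for t in m.tags))

    cands = []
    for tree in trees:
        cands.extend(_precursor_candidates(tree, library, tol_ppm))
    seen, uniq_cands = set(), []
    for rec, d in sorted(cands, key=lambda c: (c[0].compound_class != best_class, c[1])):
        if rec.compound_id not in seen:
            seen.add(rec.compound_id)
            uniq_cands.append((rec, d))

    msi = 3
    for rec, _ in uniq_cands:
        overlap = max((_spectral_overlap(t, rec) for t in trees), default=0.0)
        if overlap >= 0.6:
            rt_ok = rt is None or rec.rt_minutes is None or abs(rt - rec.rt_minutes) <= 0.5
            if rec.std and rt_ok:
                msi = 1
                break
            msi = min(msi, 2)

    # paired isomers in the library with one spectrum class suggest
    # cis/trans conformers distinguished only by retention
    formulas = {}
    for rec, _ in uniq_cands:
        if rec.formula is not None:
            formulas.setdefault((rec.formula.hill(), rec.compound_class), []).append(rec.name)
    conformer = tuple(f"possible cis/trans conformer pair: {sorted(set(v))}"
                      for k, v in formulas.items()
                      if len(v) > 1 and k[1] == best_class == "amide")
    rationale = tuple(f"{m.rule_id} [{m.confidence}] -> {m.class_assigned}"
                      for m in matches)
    return IdentificationCall(
        best_class=best_class,
        candidate_names=tuple(rec.name for rec, _ in uniq_cands),
        msi_level=msi,
        rationale=rationale,
        matches=tuple(matches),
        ambiguous=ambiguous,
        tags=tags + conformer,
    )


def replay_fixtures(library=None) -> pd.DataFrame:
    """Classify every bundled library fixture and compare with the
    curated class; 'agree' accepts an abstention (no class) for
    compounds curated outside the rule vocabulary ('other')."""
    if library is None:
        library = load_compound_library()
    rows = []
    for rec in library:
        trees = spectrum_trees(rec)
        call = identify(trees, library=library) if trees else IdentificationCall(
            None, (), 3, ())
        agree = (call.best_class == rec.compound_class
                 or (rec.compound_class == "other" and call.best_class is None))
        rows.append({
            "compound_id": rec.compound_id, "name": rec.name,
            "curated_class": rec.compound_class,
            "assigned_class": call.best_class, "agree": agree,
            "msi_level": call.msi_level, "std": rec.std,
            "ambiguous": call.ambiguous,
            "consistency_flag": rec.consistency_flag,
            "n_trees": len(trees),
        })
    return pd.DataFrame(rows)
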