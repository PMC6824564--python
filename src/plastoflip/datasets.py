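"""Curated reference data: eleven small-inversion loci characterized in a
published survey of 20 Lauraceae plastomes (17 Lindera plus Actinodaphne
lancifolia, Litsea japonica and Sassafras tzumu).

Each locus records the stem (5' arm), the published hairpin free energy,
and every observed loop form with the taxa carrying it; taxa whose stem
deviates from the reference arm are flagged. The printed constructs
serve as worked examples for orientation classification, closure and
flip-invariance checks without any genome downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

SURVEY_TAXA: list[str] = [
    "Act_lancifolia", "Lin_aggregata", "Lin_angustifolia", "Lin_chunii",
    "Lin_communis", "Lin_erythrocarpa", "Lin_floribunda", "Lin_glauca",
    "Lin_megaphylla", "Lin_metcalfiana", "Lin_nacusua", "Lin_neesiana",
    "Lin_obtusiloba", "Lin_praecox", "Lin_pulcherrima", "Lin_reflexa",
    "Lin_rubronervia", "Lin_sericea", "Lit_japonica", "Sas_tzumu",
]


@dataclass(frozen=True)
class SurveyForm:
    label: str                     # published subtype label, e.g. "A1"
    loop: str
    taxa: tuple[str, ...]
    modified: tuple[str, ...] = ()  # taxa with an altered stem arm


@dataclass(frozen=True)
class SurveyLocus:
    number: int
    region: str                    # flanking genes or gene name
    functional: str                # IGS / CDS / intron
    stem: str                      # 5' arm of the reference hairpin
    published_dg: float            # kcal/mol as printed in the survey

    forms: tuple[SurveyForm, ...] = ()

    def a_loops(self) -> list[str]:
        return [f.loop for f in self.forms if f.label.startswith("A")]

    def b_loops(self) -> list[str]:
        return [f.loop for f in self.forms if f.label.startswith("B")]

    def orientation_by_taxon(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for f in self.forms:
            for t in f.taxa:
                out[t] = f.label[0]
        return out

    def loop_by_taxon(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for f in self.forms:
            for t in f.taxa:
                out[t] = f.loop
        return out


_ALL = SURVEY_TAXA  # shorthand used below


def _others(*exclude: str) -> tuple[str, ...]:
    return tuple(t for t in _ALL if t not in exclude)


SI_SURVEY: tuple[SurveyLocus, ...] = (
    SurveyLocus(
        1, "trnH-psbA", "IGS", "TTTGATTTT", -5.60, (
            SurveyForm("A1", "TTCCT", (
                "Act_lancifolia", "Lin_aggregata", "Lin_angustifolia",
                "Lin_communis", "Lin_erythrocarpa", "Lin_glauca",
                "Lin_megaphylla", "Lin_nacusua", "Lin_praecox",
                "Lin_rubronervia", "Sas_tzumu"), ("Sas_tzumu",)),
            SurveyForm("A2", "TTCAA", (
                "Lin_chunii", "Lin_floribunda", "Lin_metcalfiana",
                "Lin_neesiana", "Lin_reflexa", "Lin_sericea"),
                ("Lin_neesiana", "Lin_sericea")),
            SurveyForm("B1", "AGGAA", (
                "Lin_obtusiloba", "Lin_pulcherrima", "Lit_japonica")),
        )),
    SurveyLocus(
        2, "trnH-psbA", "IGS", "GGATCAATACCAAACTTCTT", -20.59, (
            SurveyForm("A1", "AATAGAAC", (
                "Lin_chunii", "Lin_erythrocarpa", "Lin_megaphylla",
                "Lin_metcalfiana", "Lin_neesiana", "Lin_obtusiloba",
                "Sas_tzumu"), ("Lin_obtusiloba", "Sas_tzumu")),
            SurveyForm("A2", "AATAAAAC", ("Lin_rubronervia",)),
            SurveyForm("A3", "ATAGAA", ("Lin_angustifolia", "Lin_pulcherrima"),
                       ("Lin_angustifolia", "Lin_pulcherrima")),
            SurveyForm("A4", "ATAGAACAGAA", ("Lin_communis", "Lin_nacusua"),
                       ("Lin_communis", "Lin_nacusua")),
            SurveyForm("B1", "GTTCTATT", (
                "Act_lancifolia", "Lin_aggregata", "Lin_floribunda",
                "Lin_praecox", "Lin_reflexa", "Lin_sericea", "Lit_japonica"),
                ("Act_lancifolia", "Lin_aggregata")),
            SurveyForm("B2", "TTCTAT", ("Lin_glauca",), ("Lin_glauca",)),
        )),
    SurveyLocus(
        3, "rps16-trnQ", "IGS", "TTAATTCCA", -7.30, (
            SurveyForm("A1", "GCGA", _others("Lin_floribunda")),
            SurveyForm("B1", "TCGC", ("Lin_floribunda",)),
        )),
    SurveyLocus(
        4, "rpoB-trnC", "IGS", "TTTGATCTCC", -7.22, (
            SurveyForm("A1", "TTATGTCATTAAGGAAACCAAATT", _others(
                "Lin_communis", "Lin_nacusua", "Lin_erythrocarpa",
                "Lin_metcalfiana")),
            # the published table prints A2 with the same sequence as A1
            SurveyForm("A2", "TTATGTCATTAAGGAAACCAAATT",
                       ("Lin_communis", "Lin_nacusua")),
            SurveyForm("A3", "TTATGTCATTAAGGAAACAAAATT",
                       ("Lin_erythrocarpa",)),
            SurveyForm("B1", "AATTTGGTTTCCTTAATGACATAA",
                       ("Lin_metcalfiana",)),
        )),
    SurveyLocus(
        5, "psbC-trnS", "IGS", "TGGCTCGGCTA", -12.50, (
            SurveyForm("A1", "GGTGGGA", _others("Lin_metcalfiana")),
            SurveyForm("B1", "TCCCACC", ("Lin_metcalfiana",)),
        )),
    SurveyLocus(
        6, "petA-psbJ", "IGS", "TTTCGACACAAGAAAA", -15.98, (
            SurveyForm("A1", "TTCC", (
                "Act_lancifolia", "Lin_angustifolia", "Lin_communis",
                "Lin_erythrocarpa", "Lin_glauca", "Lin_metcalfiana",
                "Lin_nacusua", "Lin_neesiana", "Lin_obtusiloba",
                "Lin_pulcherrima", "Lin_sericea", "Lit_japonica"),
                ("Lin_angustifolia",)),
            SurveyForm("B1", "GGAA", (
                "Lin_aggregata", "Lin_chunii", "Lin_floribunda",
                "Lin_megaphylla", "Lin_praecox", "Lin_reflexa",
                "Lin_rubronervia")),
            SurveyForm("B2", "GCGGAAAATT", ("Sas_tzumu",)),
        )),
    SurveyLocus(
        7, "petA-psbJ", "IGS", "AGTAAGAACTCAATAGGACCTTACCCCT", -30.19, (
            SurveyForm("A1", "CTTTGTCTGATTCG", (
                "Lin_chunii", "Lin_floribunda", "Lin_glauca",
                "Lin_megaphylla", "Lin_nacusua", "Lin_obtusiloba",
                "Lin_pulcherrima", "Lin_reflexa", "Lin_sericea",
                "Lit_japonica", "Sas_tzumu")),
            SurveyForm("B1", "CCGAATCAGACAAAGA", (
                "Act_lancifolia", "Lin_aggregata", "Lin_angustifolia",
                "Lin_communis", "Lin_erythrocarpa", "Lin_metcalfiana",
                "Lin_neesiana", "Lin_praecox", "Lin_rubronervia")),
        )),
    SurveyLocus(
        8, "rpoA", "CDS", "ACATCTTC", -6.90, (
            SurveyForm("A1", "TATGC", _others("Lin_reflexa", "Sas_tzumu")),
            SurveyForm("B1", "GCATA", ("Lin_reflexa",)),
        )),
    SurveyLocus(
        9, "ycf2", "CDS", "TTTTTATC", -5.45, (
            SurveyForm("A1", "GAAA", _others("Lin_glauca")),
            SurveyForm("B1", "TTTC", ("Lin_glauca",)),
        )),
    SurveyLocus(
        10, "ccsA-ndhD", "IGS", "AAGTTTTTTCGAACCATTTGAATCA", -27.14, (
            SurveyForm("A1", "CTACT", (
                "Act_lancifolia", "Lin_aggregata", "Lin_angustifolia",
                "Lin_chunii", "Lin_communis", "Lin_erythrocarpa",
                "Lin_metcalfiana", "Lin_nacusua", "Lin_neesiana",
                "Lin_praecox", "Lin_rubronervia", "Lin_sericea",
                "Lit_japonica")),
            SurveyForm("B1", "AGTAG", (
                "Lin_floribunda", "Lin_glauca", "Lin_megaphylla",
                "Lin_obtusiloba", "Lin_pulcherrima", "Lin_reflexa",
                "Sas_tzumu")),
        )),
    SurveyLocus(
        11, "ndhA", "intron", "ACCCCTTTCCT", -9.23, (
            SurveyForm("A1", "GGAAATAA", (
                "Lin_aggregata", "Lin_angustifolia", "Lin_chunii",
                "Lin_communis", "Lin_erythrocarpa", "Lin_floribunda",
                "Lin_megaphylla", "Lin_metcalfiana", "Lin_nacusua",
                "Lin_neesiana", "Lin_obtusiloba", "Lin_praecox",
                "Lin_pulcherrima", "Lit_japonica")),
            SurveyForm("A2", "GGAAAGAA", ("Sas_tzumu",)),
            SurveyForm("B1", "TTATTTCC", (
                "Act_lancifolia", "Lin_glauca", "Lin_reflexa",
                "Lin_sericea")),
            SurveyForm("B2", "TTATTTAC", ("Lin_rubronervia",)),
        )),
)


def load_si_survey() -> tuple[SurveyLocus, ...]:
    """The eleven published SI loci with per-taxon loop forms."""
    return SI_SURVEY
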