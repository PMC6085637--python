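"""Reference design of the monitored conservation programs.

Constants describing the three conserved Chinese indigenous chicken breeds
whose monitoring design this package emulates: Baier Yellow Chicken (BEC),
Beijing You Chicken (BYC) and Langshan Chicken (LSC), each kept as a closed
flock of 30 sires and 300 dams under the R:F scheme and sampled at three
generations (30 birds: 10 males, 20 females). ``REPORTED_F_ROH`` carries the
published ROH-based inbreeding coefficients of the nine sub-populations,
used as an input when correlating the mating-plan expectation F_ES against
genomic inbreeding.
"""

from __future__ import annotations

from .inbreeding import InbreedingRecord, MatingPlan, f_es

__all__ = [
    "BREED_PLANS",
    "SAMPLING_YEARS",
    "REPORTED_F_ROH",
    "subpopulation_labels",
    "mating_plan_records",
]

#: Breeding census and conservation start year per breed (one generation per year).
BREED_PLANS: dict[str, MatingPlan] = {
    "BEC": MatingPlan(30, 300, 1998),
    "BYC": MatingPlan(30, 300, 1976),
    "LSC": MatingPlan(30, 300, 1998),
}

#: Sampling years per breed; labels use the last two digits (BEC07 = BEC in 2007).
SAMPLING_YEARS: dict[str, tuple[int, int, int]] = {
    "BEC": (2007, 2010, 2015),
    "BYC": (2007, 2010, 2015),
    "LSC": (2010, 2012, 2015),
}

#: Published ROH-based inbreeding coefficient per sub-population.
REPORTED_F_ROH: dict[str, float] = {
    "BEC07": 0.0500,
    "BEC10": 0.0481,
    "BEC15": 0.0553,
    "BYC07": 0.0698,
    "BYC10": 0.0613,
    "BYC15": 0.0925,
    "LSC10": 0.0474,
    "LSC12": 0.0461,
    "LSC15": 0.0606,
}


def subpopulation_labels() -> list[str]:
    return [f"{b}{str(y)[-2:]}" for b in SAMPLING_YEARS for y in SAMPLING_YEARS[b]]


def mating_plan_records() -> list[InbreedingRecord]:
    """The nine (F_ES, reported F_ROH) pairs, F_ES computed from the plans."""
    records: list[InbreedingRecord] = []
    for breed, years in SAMPLING_YEARS.items():
        plan = BREED_PLANS[breed]
        for year in years:
            label = f"{breed}{str(year)[-2:]}"
            records.append(
                InbreedingRecord(
                    subpopulation=label,
                    t=year - plan.start_year,
                    f_es=f_es(plan, year),
                    f_roh=REPORTED_F_ROH[label],
                )
            )
    return records
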