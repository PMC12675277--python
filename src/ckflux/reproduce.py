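"""Refit of the externally deposited raw accumulation data.

The raw time courses behind the published kinetic estimates for the BY-2
campaign are deposited at Zenodo (DOI 10.5281/zenodo.16568211) and are not
shipped with this package.  Once downloaded and exported to the long-format
assay schema (see :mod:`ckflux.io`), this module refits them with the same
constrained model and compares the recovered group medians of the influx
constant and the dose-response IC50 values against the previously reported
point estimates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np

from . import dose_response, fitting, io

__all__ = [
    "REPORTED_MEDIAN_I_PER_S",
    "REPORTED_IC50_NM",
    "refit_deposited",
]

#: previously reported median influx constants (s^-1) per tracer,
#: untreated BY-2 cells; comparison targets for a refit of the deposit
REPORTED_MEDIAN_I_PER_S: Dict[str, float] = {
    "tZ": 17.86e-3,
    "DHZ": 14.94e-3,
    "iP": 11.58e-3,
    "tZR": 3.45e-3,
    "DHZR": 2.38e-3,
    "iPR": 5.44e-3,
    "BA": 9.14e-3,
    "BAR": 16.22e-3,
}

#: previously reported IC50 values (nM) for tracer vs unlabelled competitor
REPORTED_IC50_NM: Dict[Tuple[str, str], float] = {
    ("tZ", "tZ"): 112.21,
    ("tZR", "tZR"): 2330.0,
    ("iP", "iP"): 27.25,
    ("iPR", "iPR"): 2650.0,
}


def refit_deposited(
    assays_csv: Union[str, Path],
) -> Tuple[Dict[str, float], Dict[Tuple[str, str], float]]:
    """Refit a deposited accumulation table and summarise it.

    The table must follow the long-format assay schema with ``tracer`` (and,
    for dose-response series, ``competitor`` and ``competitor_conc_nM``)
    metadata.  Assays are jointly fitted per tracer with shared efflux and
    adsorption parameters; per-tracer medians of the influx constant and,
    where a competitor ladder is present, fitted IC50 values are returned.

    Raises ``FileNotFoundError`` when the deposit has not been downloaded.
    """
    assays_csv = Path(assays_csv)
    if not assays_csv.exists():
        raise FileNotFoundError(
            f"{assays_csv} not found: download the raw data deposit "
            "(DOI 10.5281/zenodo.16568211), export it to the long-format assay "
            "schema and point this function at the resulting CSV"
        )
    dataset = io.read_assays(assays_csv)
    by_tracer: Dict[str, list] = {}
    for a in dataset.assays:
        by_tracer.setdefault(str(a.condition.get("tracer", "")), []).append(a)

    medians: Dict[str, float] = {}
    ic50s: Dict[Tuple[str, str], float] = {}
    for tracer, assays in by_tracer.items():
        sub = fitting.AssayDataset(
            assays=assays, f=dataset.f, grouping={a.assay_id: tracer for a in assays}
        )
        fit = fitting.fit_dataset_shared(sub)
        medians[tracer] = float(np.median([p.I for p in fit.params.values()]))
        ladder = sorted(
            {
                (str(a.condition.get("competitor", "")), float(a.condition["competitor_conc_nM"]))
                for a in assays
                if "competitor_conc_nM" in a.condition
            }
        )
        competitors = {c for c, _ in ladder}
        for comp in competitors:
            points = sorted(
                (float(a.condition["competitor_conc_nM"]), fit.params[a.assay_id].I)
                for a in assays
                if str(a.condition.get("competitor", "")) == comp
                and "competitor_conc_nM" in a.condition
            )
            if len(points) < 4:
                continue
            series = dose_response.DoseResponseSeries(
                competitor_conc=[p[0] for p in points],
                I_values=[p[1] for p in points],
                tracer=tracer,
                competitor=comp,
            )
            sat = dose_response.fit_saturation(series)
            if not sat.no_saturation:
                ic50s[(tracer, comp)] = sat.params.ic50
    return medians, ic50s
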