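"""Published out-of-sample error grids for three national age-structure series.

A reference study of compositional age-structure forecasting reports, for
China, India and Vietnam (World Bank shares, 48-year training window,
9-year test window), the CoDa-RMSE and CoDa-MAPE of every pairing of a
constraint-removal transform (LCC.Y, LCC.M, LCC.O, ILR, DRHT, plus
untransformed "Base" runs) with a forecasting family (ARIMA, ETS, VAR,
NNETTS).  The grids are reproduced here as fixtures so the selection rule
can be exercised against known published values without re-downloading
the underlying national statistics (whose vintage is not archived).

Values are (CoDa-RMSE, CoDa-MAPE-in-percent) per cell.
"""

from __future__ import annotations

from .pipeline import CellResult, EvaluationReport

_GRIDS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "china": {
        ("LCC.Y", "ARIMA"): (0.09, 6.10), ("LCC.Y", "ETS"): (0.09, 6.10),
        ("LCC.Y", "VAR"): (0.17, 11.48), ("LCC.Y", "NNETTS"): (0.14, 9.73),
        ("LCC.M", "ARIMA"): (0.07, 4.87), ("LCC.M", "ETS"): (0.09, 6.17),
        ("LCC.M", "VAR"): (0.17, 11.48), ("LCC.M", "NNETTS"): (0.06, 3.94),
        ("LCC.O", "ARIMA"): (0.09, 6.24), ("LCC.O", "ETS"): (0.09, 6.17),
        ("LCC.O", "VAR"): (0.17, 11.48), ("LCC.O", "NNETTS"): (0.13, 8.67),
        ("ILR", "ARIMA"): (0.06, 3.94), ("ILR", "ETS"): (0.08, 5.38),
        ("ILR", "VAR"): (0.10, 6.61), ("ILR", "NNETTS"): (0.08, 5.50),
        ("DRHT", "ARIMA"): (0.08, 5.67), ("DRHT", "ETS"): (0.08, 5.67),
        ("DRHT", "VAR"): (0.10, 6.91), ("DRHT", "NNETTS"): (0.06, 4.21),
        ("Base", "ARIMA"): (0.08, 5.10), ("Base", "ETS"): (0.09, 6.09),
        ("Base", "VAR"): (0.17, 11.48), ("Base", "NNETTS"): (0.15, 10.22),
    },
    "india": {
        ("LCC.Y", "ARIMA"): (0.02, 1.06), ("LCC.Y", "ETS"): (0.01, 0.83),
        ("LCC.Y", "VAR"): (0.02, 1.11), ("LCC.Y", "NNETTS"): (0.07, 4.06),
        ("LCC.M", "ARIMA"): (0.02, 1.09), ("LCC.M", "ETS"): (0.01, 0.83),
        ("LCC.M", "VAR"): (0.02, 1.11), ("LCC.M", "NNETTS"): (0.10, 5.64),
        ("LCC.O", "ARIMA"): (0.02, 1.28), ("LCC.O", "ETS"): (0.01, 0.84),
        ("LCC.O", "VAR"): (0.02, 1.11), ("LCC.O", "NNETTS"): (0.26, 14.78),
        ("ILR", "ARIMA"): (0.02, 1.09), ("ILR", "ETS"): (0.01, 0.81),
        ("ILR", "VAR"): (0.03, 1.61), ("ILR", "NNETTS"): (0.02, 0.93),
        ("DRHT", "ARIMA"): (0.02, 1.07), ("DRHT", "ETS"): (0.01, 0.81),
        ("DRHT", "VAR"): (0.02, 1.11), ("DRHT", "NNETTS"): (0.28, 15.33),
        ("Base", "ARIMA"): (0.02, 1.09), ("Base", "ETS"): (0.02, 0.90),
        ("Base", "VAR"): (0.02, 1.11), ("Base", "NNETTS"): (0.08, 4.81),
    },
    "vietnam": {
        ("LCC.Y", "ARIMA"): (0.10, 6.16), ("LCC.Y", "ETS"): (0.08, 5.00),
        ("LCC.Y", "VAR"): (0.07, 4.35), ("LCC.Y", "NNETTS"): (0.06, 3.43),
        ("LCC.M", "ARIMA"): (0.10, 6.11), ("LCC.M", "ETS"): (0.08, 5.00),
        ("LCC.M", "VAR"): (0.07, 4.35), ("LCC.M", "NNETTS"): (0.17, 10.22),
        ("LCC.O", "ARIMA"): (0.10, 6.05), ("LCC.O", "ETS"): (0.08, 4.99),
        ("LCC.O", "VAR"): (0.07, 4.35), ("LCC.O", "NNETTS"): (0.62, 37.12),
        ("ILR", "ARIMA"): (0.08, 4.64), ("ILR", "ETS"): (0.07, 4.14),
        ("ILR", "VAR"): (0.07, 4.41), ("ILR", "NNETTS"): (0.24, 14.33),
        ("DRHT", "ARIMA"): (0.09, 5.69), ("DRHT", "ETS"): (0.07, 4.49),
        ("DRHT", "VAR"): (0.07, 4.27), ("DRHT", "NNETTS"): (0.44, 26.37),
        ("Base", "ARIMA"): (0.10, 6.12), ("Base", "ETS"): (0.07, 4.10),
        ("Base", "VAR"): (0.07, 4.35), ("Base", "NNETTS"): (0.07, 4.51),
    },
}

COUNTRIES = tuple(_GRIDS)


def benchmark_report(country: str) -> EvaluationReport:
    """The published error grid for one country as an EvaluationReport."""
    try:
        grid = _GRIDS[country]
    except KeyError:
        raise KeyError(
            f"unknown country {country!r}; valid names: {sorted(_GRIDS)}"
        ) from None
    entries = {
        key: CellResult(coda_rmse=rmse, coda_mape=mape)
        for key, (rmse, mape) in grid.items()
    }
    return EvaluationReport(
        entries=entries, train_years=(1960, 2007), test_years=(2008, 2016)
    )
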