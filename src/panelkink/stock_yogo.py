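"""Bundled Stock–Yogo weak-instrument critical values.

Keys are ``(n_endogenous, n_instruments, criterion)`` where criterion names
the tabulated row: ``bias_X`` is the maximal relative bias of 2SLS (X percent)
and ``size_X`` the maximal size of the nominal 5% 2SLS Wald test.  Only the
rows of the published tabulation bundled here are available; unknown keys
raise :class:`~panelkink.exceptions.TableLookupError` listing what exists.
The bias rows require at least two overidentifying restrictions, which is why
they start at three instruments.
"""

from .exceptions import TableLookupError

CRITICAL_VALUES: dict[tuple[int, int, str], float] = {}

_ONE_ENDOG = {
    "bias_5":  {3: 13.91, 4: 16.85, 5: 18.37, 6: 19.28, 7: 19.86, 8: 20.25},
    "bias_10": {3: 9.08, 4: 10.27, 5: 10.83, 6: 11.12, 7: 11.29, 8: 11.39},
    "bias_20": {3: 6.46, 4: 6.71, 5: 6.77, 6: 6.76, 7: 6.73, 8: 6.69},
    "bias_30": {3: 5.39, 4: 5.34, 5: 5.25, 6: 5.15, 7: 5.07, 8: 4.99},
    "size_10": {1: 16.38, 2: 19.93, 3: 22.30, 4: 24.58, 5: 26.87, 6: 29.18, 7: 31.50, 8: 33.84},
    "size_15": {1: 8.96, 2: 11.59, 3: 12.83, 4: 13.96, 5: 15.09, 6: 16.23, 7: 17.38, 8: 18.54},
    "size_20": {1: 6.66, 2: 8.75, 3: 9.54, 4: 10.26, 5: 10.98, 6: 11.72, 7: 12.48, 8: 13.24},
    "size_25": {1: 5.53, 2: 7.25, 3: 7.80, 4: 8.31, 5: 8.84, 6: 9.38, 7: 9.93, 8: 10.50},
}
for crit, row in _ONE_ENDOG.items():
    for k, v in row.items():
        CRITICAL_VALUES[(1, k, crit)] = v

# two endogenous regressors, maximal 10% size of the 5% Wald test
for k, v in {2: 7.03, 3: 13.43, 4: 16.87}.items():
    CRITICAL_VALUES[(2, k, "size_10")] = v


def stock_yogo_lookup(n_endog: int, n_instruments: int, criterion: str) -> float:
    """Tabulated Stock–Yogo critical value for the given configuration."""
    key = (int(n_endog), int(n_instruments), str(criterion))
    try:
        return CRITICAL_VALUES[key]
    except KeyError:
        available = sorted(CRITICAL_VALUES)
        raise TableLookupError(
            f"no tabulated critical value for {key}; available keys: {available}"
        ) from None
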