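"""Published comparison-table cells, stored as printed strings.

Layout: three (A, alpha) panels; within each panel six models in canonical
order; six values per row — block (var_S=6, var_T=8) at p = 0.3, 0.5, 0.7,
then block (var_S=10, var_T=4) at the same p values.  Population mu_Y = 10,
var_Y = 2, n = 500 throughout.

Values are kept as strings so each cell's own printed precision (the
tables mix 2-6 decimals) drives the comparison tolerance of 0.5 ulp at
that precision.
"""

PANELS = ((0.8, 0.9), (0.5, 0.6), (0.2, 0.3))
BLOCKS = ((6.0, 8.0), (10.0, 4.0))
P_VALUES = (0.3, 0.5, 0.7)

MODEL_ORDER = (
    "warner_additive",
    "eichhorn_hayre",
    "gupta_optional_additive",
    "barlev_optional_multiplicative",
    "murtaza_mixed",
    "gupta_mixed_optional",
)

# variance of the mean estimator, Var(mu_hat)
VARIANCE = {
    (0.8, 0.9): {
        "warner_additive": ("0.016", "0.016", "0.016", "0.024", "0.024", "0.024"),
        "eichhorn_hayre": ("1.636", "1.636", "1.636", "0.82", "0.82", "0.82"),
        "gupta_optional_additive": ("0.0124", "0.01", "0.0076", "0.018", "0.014", "0.01"),
        "barlev_optional_multiplicative": ("1.1464", "0.82", "0.4936", "0.5752", "0.412", "0.2488"),
        "murtaza_mixed": ("1.15612", "0.82972", "0.50332", "0.5914", "0.4282", "0.265"),
        "gupta_mixed_optional": ("0.24088", "0.1732", "0.10552", "0.13224", "0.0956", "0.05896"),
    },
    (0.5, 0.6): {
        "warner_additive": ("0.016", "0.016", "0.016", "0.024", "0.024", "0.024"),
        "eichhorn_hayre": ("1.636", "1.636", "1.636", "0.82", "0.82", "0.82"),
        "gupta_optional_additive": ("0.0124", "0.01", "0.0076", "0.018", "0.014", "0.01"),
        "barlev_optional_multiplicative": ("1.1464", "0.82", "0.4936", "0.5752", "0.412", "0.2488"),
        "murtaza_mixed": ("1.15072", "0.82432", "0.49792", "0.5824", "0.4192", "0.256"),
        "gupta_mixed_optional": ("0.5836", "0.418", "0.2524", "0.3036", "0.218", "0.1324"),
    },
    (0.2, 0.3): {
        "warner_additive": ("0.016", "0.016", "0.016", "0.024", "0.024", "0.024"),
        "eichhorn_hayre": ("1.636", "1.636", "1.636", "0.82", "0.82", "0.82"),
        "gupta_optional_additive": ("0.0124", "0.01", "0.0076", "0.018", "0.014", "0.01"),
        "barlev_optional_multiplicative": ("1.1464", "0.82", "0.4936", "0.5752", "0.412", "0.2488"),
        "murtaza_mixed": ("1.14748", "0.82108", "0.49468", "0.577", "0.4138", "0.2506"),
        "gupta_mixed_optional": ("0.92632", "0.6628", "0.39928", "0.47496", "0.3404", "0.20584"),
    },
}

# privacy measure nabla = E[(Z - Y)^2] (published closed forms)
PRIVACY = {
    (0.8, 0.9): {
        "warner_additive": ("6", "6", "6", "10", "10", "10"),
        "eichhorn_hayre": ("816", "816", "816", "408", "408", "408"),
        "gupta_optional_additive": ("4.2", "3", "1.8", "7", "5", "3"),
        "barlev_optional_multiplicative": ("571.2", "408", "244.8", "285.6", "204", "122.4"),
        "murtaza_mixed": ("574.6", "410.43", "246.26", "291.27", "208.05", "124.83"),
        "gupta_mixed_optional": ("169.2", "169.2", "169.2", "91.6", "91.6", "91.6"),
    },
    (0.5, 0.6): {
        "warner_additive": ("6", "6", "6", "10", "10", "10"),
        "eichhorn_hayre": ("816", "816", "816", "408", "408", "408"),
        "gupta_optional_additive": ("4.2", "3", "1.8", "7", "5", "3"),
        "barlev_optional_multiplicative": ("571.2", "408", "244.8", "285.6", "204", "122.4"),
        "murtaza_mixed": ("572.71", "409.08", "245.45", "288.12", "205.8", "123.48"),
        "gupta_mixed_optional": ("414", "414", "414", "214", "214", "214"),
    },
    (0.2, 0.3): {
        "warner_additive": ("6", "6", "6", "10", "10", "10"),
        "eichhorn_hayre": ("816", "816", "816", "408", "408", "408"),
        "gupta_optional_additive": ("4.2", "3", "1.8", "7", "5", "3"),
        "barlev_optional_multiplicative": ("571.2", "408", "244.8", "285.6", "204", "122.4"),
        "murtaza_mixed": ("571.58", "408.27", "244.96", "286.23", "204.45", "122.67"),
        "gupta_mixed_optional": ("658.8", "658.8", "658.8", "336.4", "336.4", "336.4"),
    },
}

# joint efficiency-privacy measure delta = Var(mu_hat) / nabla
DELTA = {
    (0.8, 0.9): {
        "warner_additive": ("0.002667", "0.002667", "0.002667", "0.0024", "0.0024", "0.0024"),
        "eichhorn_hayre": ("0.002005", "0.002005", "0.002005", "0.00201", "0.00201", "0.00201"),
        "gupta_optional_additive": ("0.002952", "0.003333", "0.004222", "0.002571", "0.0028", "0.003333"),
        "barlev_optional_multiplicative": ("0.002007", "0.00201", "0.002016", "0.002014", "0.00202", "0.002033"),
        "murtaza_mixed": ("0.002012", "0.002022", "0.002044", "0.00203", "0.002058", "0.002123"),
        "gupta_mixed_optional": ("0.001424", "0.001024", "0.000624", "0.001444", "0.001044", "0.000644"),
    },
    (0.5, 0.6): {
        "warner_additive": ("0.002667", "0.002667", "0.002667", "0.0024", "0.0024", "0.0024"),
        "eichhorn_hayre": ("0.002005", "0.002005", "0.002005", "0.00201", "0.00201", "0.00201"),
        "gupta_optional_additive": ("0.002952", "0.003333", "0.004222", "0.002571", "0.0028", "0.003333"),
        "barlev_optional_multiplicative": ("0.002007", "0.00201", "0.002016", "0.002014", "0.00202", "0.002033"),
        "murtaza_mixed": ("0.002009", "0.002015", "0.002029", "0.002021", "0.002037", "0.002073"),
        "gupta_mixed_optional": ("0.00141", "0.00101", "0.00061", "0.001419", "0.001019", "0.000619"),
    },
    (0.2, 0.3): {
        "warner_additive": ("0.002667", "0.002667", "0.002667", "0.0024", "0.0024", "0.0024"),
        "eichhorn_hayre": ("0.002005", "0.002005", "0.002005", "0.00201", "0.00201", "0.00201"),
        "gupta_optional_additive": ("0.002952", "0.003333", "0.004222", "0.002571", "0.0028", "0.003333"),
        "barlev_optional_multiplicative": ("0.002007", "0.00201", "0.002016", "0.002014", "0.00202", "0.002033"),
        "murtaza_mixed": ("0.002008", "0.002011", "0.002019", "0.002016", "0.002024", "0.002043"),
        "gupta_mixed_optional": ("0.001406", "0.001006", "0.000606", "0.001412", "0.001012", "0.000612"),
    },
}

TABLES = {"variance": VARIANCE, "privacy": PRIVACY, "delta": DELTA}


def printed_decimals(cell: str) -> int:
    """Number of decimal places a printed cell shows."""
    return len(cell.split(".")[1]) if "." in cell else 0


def printed_tolerance(cell: str) -> float:
    """Half a unit in the last printed decimal place (0.5 ulp)."""
    return 0.5 * 10.0 ** (-printed_decimals(cell)) * (1.0 + 1e-9)


def iter_cells(metric: str):
    """Yield (panel, block_idx, p, model, printed_string) over all 108 cells."""
    table = TABLES[metric]
    for panel in PANELS:
        for model in MODEL_ORDER:
            row = table[panel][model]
            for j, value in enumerate(row):
                block_idx, p = divmod(j, len(P_VALUES))
                yield panel, block_idx, P_VALUES[p], model, value
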