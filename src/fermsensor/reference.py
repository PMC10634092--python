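"""Published reference mutual-information table for a pilot-scale run.

Mutual information (nats) between the 16 online environmental channels and
the dominant fermentation variables, as reported for a pilot-scale
*Pichia pastoris* fed-batch process partitioned into four query domains.
The table serves as a worked example for the ranking/selection logic: in
each domain the top six channels by MI form that domain's soft-sensor
signature.
"""

#: variable -> (QD1, QD2, QD3, QD4)
REFERENCE_MI = {
    "DO":      (1.16, 1.23, 1.11, 1.09),
    "eta_CO2": (1.05, 1.10, 1.13, 1.07),
    "pH":      (0.65, 0.62, 0.61, 0.59),
    "f_b":     (0.73, 0.72, 0.69, 0.71),
    "P_tank":  (0.12, 0.21, 0.10, 0.32),
    "l":       (0.21, 0.36, 0.35, 0.32),
    "t_ferm":  (1.39, 1.45, 1.30, 1.35),
    "f_w":     (0.90, 0.96, 1.05, 0.97),
    "f_a":     (0.85, 0.79, 0.72, 0.71),
    "f_f":     (0.83, 1.21, 1.04, 0.80),
    "f_c":     (0.44, 0.82, 0.77, 0.81),
    "T":       (0.31, 0.35, 0.29, 0.32),
    "r":       (0.19, 0.23, 0.20, 0.17),
    "f_e":     (0.46, 0.81, 0.86, 0.73),
    "f_d":     (0.28, 0.35, 0.41, 0.39),
    "V":       (0.76, 0.71, 0.76, 0.75),
}

N_DOMAINS = 4


def reference_mi_for_domain(domain: int) -> dict:
    """MI map {variable: value} for one query domain (1-based index)."""
    if not 1 <= domain <= N_DOMAINS:
        raise ValueError(f"domain must be in 1..{N_DOMAINS}")
    return {name: vals[domain - 1] for name, vals in REFERENCE_MI.items()}
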