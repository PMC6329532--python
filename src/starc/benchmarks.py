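"""Published reference s-scores for thirty protein superfamily benchmarks.

These are the s-scores reported for four direct-coupling methods — CCMpred
(CCM), EVcouplings pseudo-likelihood (EVC), GaussDCA with Frobenius ranking
(GSF) and PSICOV (PCV) — run on thirty superfamily alignments and scored
against reference crystal structures with a 5 A contact criterion and five
intervening residues minimum.  They are carried here as input data for
summary arithmetic, method-comparison examples and regression checks; the
scoring machinery in this package does not depend on them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SUPERFAMILY_S",
    "SUPERFAMILY_S_NO_PB",
    "BENCHMARK_QUERIES",
    "column_means",
    "RAN_TRANSITION_S_R4",
    "RAN_GROUND_S_R4",
    "INITIAL_CLUSTER_SUMMARIES",
    "GNA1_FAMILY_PATTERN",
    "GNAT_SUPERFAMILY_PATTERN",
]

BENCHMARK_QUERIES = (
    "1ayaA", "1b5oA", "1el3A", "1k30A", "1b23P", "1olzA", "1wznA", "1z0kC",
    "1zp9A", "2b61A", "3ex7H", "4ag9A", "5dfiA", "5hf7A", "5m4pA", "1ijxA",
    "2nrlA", "4cmlA", "1jw9B", "3fhkF", "3h7uA", "1g9rA", "4em8A", "1i6mA",
    "3f1lA", "1jr3A", "1nnlA", "1frwA", "1bqbA", "2ovdA",
)

# s-scores per query, columns: CCM, EVC, GSF, PCV
SUPERFAMILY_S = {
    "CCM": np.array([55, 862, 612, 110, 167, 187, 169, 212, 105, 294, 254,
                     167, 293, 125, 33, 24, 98, 244, 331, 61, 589, 283, 184,
                     321, 454, 377, 136, 193, 333, 62], dtype=float),
    "EVC": np.array([54, 810, 588, 114, 135, 245, 156, 181, 110, 290, 239,
                     174, 317, 126, 34, 25, 95, 247, 318, 64, 573, 264, 181,
                     312, 448, 373, 133, 179, 336, 75], dtype=float),
    "GSF": np.array([60, 774, 514, 90, 109, 185, 159, 202, 91, 284, 173,
                     173, 244, 72, 37, 19, 68, 266, 272, 67, 502, 281, 160,
                     198, 433, 258, 111, 213, 254, 53], dtype=float),
    "PCV": np.array([43, 606, 502, 77, 101, 92, 154, 178, 86, 274, 157,
                     163, 193, 66, 23, 20, 58, 177, 243, 49, 481, 212, 146,
                     166, 397, 245, 91, 168, 190, 42], dtype=float),
}

# the same analyses scored without the ball-in-urn component
SUPERFAMILY_S_NO_PB = {
    "CCM": np.array([56, 860, 607, 110, 167, 184, 164, 209, 106, 294, 251,
                     164, 291, 126, 34, 25, 97, 242, 325, 61, 577, 275, 173,
                     316, 446, 373, 137, 194, 325, 63], dtype=float),
    "EVC": np.array([55, 805, 582, 112, 134, 240, 152, 180, 111, 290, 237,
                     171, 313, 125, 36, 25, 94, 242, 312, 64, 565, 254, 175,
                     309, 439, 365, 131, 180, 331, 75], dtype=float),
    "GSF": np.array([62, 768, 509, 90, 109, 183, 155, 201, 92, 284, 173,
                     170, 242, 73, 38, 20, 69, 264, 269, 68, 494, 274, 153,
                     194, 426, 258, 111, 212, 252, 53], dtype=float),
    "PCV": np.array([44, 601, 499, 78, 102, 91, 149, 175, 87, 275, 156,
                     163, 193, 66, 24, 21, 58, 176, 242, 49, 473, 208, 138,
                     165, 393, 245, 93, 169, 190, 41], dtype=float),
}


def column_means(table: dict | None = None) -> dict:
    """Mean s-score per method over the thirty benchmark analyses."""
    table = SUPERFAMILY_S if table is None else table
    return {k: float(np.mean(v)) for k, v in table.items()}


# Ran GTPase scored on the R4 (Rab/Rho/Ras/Ran) family couplings against the
# four crystallographically independent subunits (chains A, D, J, G) of the
# transition-state and ground-state ternary complexes.
RAN_TRANSITION_S_R4 = np.array([95.0, 96.4, 94.5, 93.2])
RAN_GROUND_S_R4 = np.array([70.0, 71.1, 72.7, 69.3])

# Reference initial-cluster geometries for two published arrays: counts from
# which the cluster-occupancy summaries (d/D and X/L percentages) derive.
INITIAL_CLUSTER_SUMMARIES = {
    # Ran GTPase array, contact-distinguished (<= 5 A)
    "ran_contacts": {"L": 12090, "D": 346, "X": 291, "d": 186, "S": 230.0},
    # Gna1 array, contact-distinguished incl. homodimer interface (<= 5 A)
    "gna1_contacts": {"L": 8534, "D": 260, "X": 663, "d": 144, "S": 91.0},
    # pattern-pair distinguished variants of the same arrays
    "ran_pattern": {"L": 12090, "D": 281, "X": 772, "d": 46, "S": 6.2},
    "gna1_pattern": {"L": 8534, "D": 263, "X": 1238, "d": 114, "S": 27.9},
}

# Pattern residue positions (by decreasing pattern score) characteristic of
# the Gna1 family and of the wider GNAT superfamily.
GNA1_FAMILY_PATTERN = (
    135, 90, 92, 104, 68, 95, 93, 44, 141, 136, 43, 102, 105, 134, 40, 58,
    36, 101, 98, 94, 35, 116, 89, 54, 61,
)
GNAT_SUPERFAMILY_PATTERN = (
    153, 116, 83, 118, 154, 103, 31, 121, 113, 24, 106, 82, 108, 117, 145,
    149, 137, 25, 148, 73, 36, 122, 79,
)
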