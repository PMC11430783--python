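"""Published summary statistics of the RNALocate v2.0-derived benchmark.

The widely used multi-label mRNA localization benchmark (36,971 sequences
after 80% CD-HIT-EST redundancy reduction, nine compartments) is distributed
with printed summary tables rather than a canonical label matrix.  The
counts below are those printed tables; :func:`rnaloc.simulate.benchmark_fixture`
realizes a synthetic dataset that reproduces them exactly.
"""

from __future__ import annotations

from .dataset import DEFAULT_COMPARTMENTS

#: Number of sequences annotated with exactly 1..9 compartments.
CARDINALITY_HISTOGRAM: tuple[int, ...] = (
    12884, 4060, 3442, 3165, 3518, 4258, 4079, 1443, 122,
)

#: Total number of sequences in the benchmark.
TOTAL_SEQUENCES: int = 36_971

#: Per-compartment sequence counts, ordered as DEFAULT_COMPARTMENTS,
#: as (total, training-validation, independent test) under the published
#: 9:1 division.
PER_LABEL_SPLIT: dict[str, tuple[int, int, int]] = {
    "exosome": (31_448, 28_304, 3_144),
    "nucleus": (21_439, 19_301, 2_138),
    "nucleoplasm": (14_237, 12_807, 1_430),
    "chromatin": (14_328, 12_893, 1_435),
    "cytoplasm": (4_016, 3_597, 419),
    "nucleolus": (11_124, 10_000, 1_124),
    "cytosol": (16_312, 14_686, 1_626),
    "membrane": (6_739, 6_047, 692),
    "ribosome": (8_680, 7_796, 884),
}

#: Per-compartment totals in universe order.
PER_LABEL_TOTALS: tuple[int, ...] = tuple(
    PER_LABEL_SPLIT[label][0] for label in DEFAULT_COMPARTMENTS
)

assert sum(CARDINALITY_HISTOGRAM) == TOTAL_SEQUENCES
# label assignments are conserved: sum_c c*hist[c] == sum of per-label totals
assert sum((c + 1) * n for c, n in enumerate(CARDINALITY_HISTOGRAM)) == sum(
    PER_LABEL_TOTALS
)
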