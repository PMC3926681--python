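"""Reference k-mer sweep statistics for Hevea brasiliensis tissue assemblies.

Published N50-vs-k-mer series (k 51-77, step 2) for de novo assemblies of
rubber-tree bark, latex and leaf paired-end RNA-Seq reads at incremental
read depths, together with the transcript-mapping percentages of the
optimized sub-assemblies against the full 16 Gb bark transcriptome
(87,612 transcripts).  These printed series are used as worked examples:
feeding them to :func:`satmap.metrics.find_optimized_kmer` must recover
every highlighted optimum (e.g. k=73 / N50 2,068 bp for the 16 Gb bark
assembly) and flag the shallow 1 Gb bark and leaf series as non-peaked.

Keys of the series dicts are datasizes in Gb; values are ordered
``(k, n50_bp)`` tuples.
"""
from __future__ import annotations

K_VALUES = tuple(range(51, 78, 2))

# N50 (bp) per k for incremental bark assemblies (1-16 Gb)
BARK_N50 = {
    1: (1389, 1375, 1353, 1343, 1315, 1288, 1255, 1225, 1199, 1147, 1111, 1068, 1034, 982),
    3: (1734, 1763, 1783, 1798, 1799, 1804, 1791, 1782, 1753, 1731, 1691, 1652, 1606, 1550),
    5: (1741, 1797, 1832, 1852, 1876, 1891, 1889, 1900, 1892, 1895, 1878, 1846, 1808, 1770),
    8: (1695, 1778, 1834, 1872, 1905, 1926, 1959, 1966, 1970, 1976, 1974, 1967, 1946, 1923),
    10: (1648, 1741, 1813, 1864, 1901, 1933, 1959, 1980, 1997, 2007, 2017, 2010, 1997, 1967),
    13: (1599, 1701, 1798, 1861, 1903, 1940, 1969, 1989, 2010, 2024, 2036, 2040, 2041, 2022),
    16: (1542, 1654, 1758, 1828, 1880, 1928, 1956, 1988, 2025, 2043, 2061, 2068, 2066, 2057),
}

# total transcript counts matching BARK_N50 (same k order)
BARK_TRANSCRIPTS = {
    1: (68942, 64265, 59325, 54670, 50440, 46261, 42626, 39223, 35773, 32606, 29621, 26674, 23699, 20746),
    3: (102352, 94288, 86117, 78651, 72051, 65903, 60666, 55645, 51333, 47383, 43910, 40633, 37433, 34531),
    5: (131979, 120998, 110086, 100131, 91351, 83027, 75893, 69159, 63469, 58112, 53357, 49412, 45312, 41621),
    8: (170838, 157127, 142292, 129469, 117384, 106569, 96676, 87780, 80153, 72612, 66249, 60561, 55384, 50636),
    10: (193885, 178204, 161486, 146550, 133175, 120901, 109522, 98782, 90055, 81560, 74220, 67593, 61680, 56233),
    13: (224292, 206355, 186542, 169917, 154642, 139498, 126478, 115028, 104399, 94500, 85874, 77667, 70331, 63767),
    16: (254026, 234717, 212283, 192775, 176018, 159832, 143857, 130546, 118385, 106974, 96653, 87612, 79038, 71504),
}

LATEX_N50 = {
    1: (706, 716, 724, 717, 707, 683, 668, 657, 642, 629, 610, 591, 578, 567),
    3: (1016, 1058, 1093, 1102, 1108, 1100, 1090, 1067, 1041, 1001, 956, 907, 850, 815),
    5: (1053, 1135, 1187, 1231, 1266, 1281, 1270, 1266, 1241, 1201, 1151, 1103, 1052, 990),
}

LEAF_N50 = {
    1: (544, 535, 523, 517, 509, 500, 490, 478, 466, 451, 439, 432, 427, 427),
    3: (831, 888, 915, 933, 937, 933, 912, 885, 855, 810, 761, 713, 669, 631),
    5: (845, 920, 999, 1049, 1079, 1086, 1084, 1059, 1026, 988, 944, 879, 823, 763),
}

# datasize (Gb) -> expected (optimized_k, optimized_n50) for peaked series
BARK_OPTIMA = {3: (61, 1804), 5: (65, 1900), 8: (69, 1976), 10: (71, 2017), 13: (75, 2041), 16: (73, 2068)}
LATEX_OPTIMA = {1: (55, 724), 3: (59, 1108), 5: (61, 1281)}
LEAF_OPTIMA = {3: (59, 937), 5: (61, 1086)}

# percent of the 87,612 full-transcriptome bark transcripts hit by each
# optimized sub-assembly (16 Gb maps to itself, hence 100).
BARK_OPTIMIZED_PCT = {3: 87.21, 5: 89.48, 8: 91.46, 10: 92.60, 13: 92.12, 16: 100.0}

# bark library read-processing tallies (reads, bases)
BARK_RAW = (169_887_626, 16_988_762_600)
BARK_PAIRED = (163_316_702, 15_726_859_825)


def series(table: dict, datasize_gb: int) -> list[tuple[int, int]]:
    """(k, n50) pairs for one datasize column of a reference table."""
    return list(zip(K_VALUES, table[datasize_gb]))
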