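"""Pipeline constants.

Every filtering/calibration threshold used anywhere in the package is
defined here with its standard default, and is overridable through the
relevant function or config argument.
"""

# --- substitution filters ---
BASE_QUALITY_THRESHOLD = 25       # mutant reads must exceed this BQ ...
BASE_QUALITY_FRACTION = (1, 3)    # ... for at least this fraction (num, den) of them
MIN_MEAN_MAPPING_QUALITY = 21
READ_END_BP = 15                  # calls supported only by first/last N bp are dropped
INDEL_PROXIMITY_BP = 10           # +REP when the nearby indel has REP>0
REPEAT_REGION = (16129, 16430)    # 1-based inclusive simple-repeat interval

# --- indel filters ---
INDEL_MIN_STRAND_READS = 3        # >=3 on one strand, or ...
INDEL_MIN_BOTH_STRAND_READS = 2   # ... >=2 on both
INDEL_PINDEL_CHECK_THRESHOLD = 4  # >=4 pindel reads triggers the bwa-support check

# --- somatic classification ---
GERMLINE_VAF_THRESHOLD = 0.9      # shared tumour/host calls above this are germline
LOW_COVERAGE_HOST_X = 20          # hosts below this mean coverage are "low coverage"
LOW_COVERAGE_TUMOUR_VAF = 0.5     # tumour VAF floor when the matched host is low coverage
DEFAULT_VAF_CUTOFF = 0.5          # host-less tumours; per-tumour override (e.g. 0.6)
HEAVY_CONTAMINATION_LEVEL = 0.4   # above this, host-less tumours use the related-tumour rule
HOMOPLASMIC_CLASS_FRACTION = 0.7  # tumour-unique VAFs >= frac*max count as homoplasmic-class

# --- copy number ---
PLOIDY = 2
HIGH_COVERAGE_X = 300             # samples above this mtDNA coverage are excluded

# --- clade timing ---
NUCLEAR_CALIBRATION_YEARS = 460
GENERATIONS_PER_MUTATION = 1000   # one homoplasmic mtDNA mutation per ~1000 generations
MIN_GENERATION_DAYS = 4
MAX_GENERATION_DAYS = 20
HUMAN_CALIBRATED_RATE = 0.025     # mutations / year
DAYS_PER_YEAR = 365.25

# --- quality-exclusion and rescue tables (position, "REF>ALT") ---
EXCLUDED_SITES = [
    (15493, "G>A"),
    (15505, "T>C"),
    (15632, "C>T"),
    (15639, "T>A"),
    (15639, "T>G"),
    (15931, "A>G"),
    (16672, "C>T"),
    (16705, "C>T"),
]

RESCUE_LIST = [
    (381, "T>A"),
    (1481, "T>C"),
    (1683, "T>C"),
    (2682, "G>A"),
    (2683, "G>A"),
    (3028, "A>C"),
    (6629, "T>C"),
    (6882, "A>G"),
    (7014, "T>G"),
    (8281, "T>C"),
    (8368, "C>T"),
    (8703, "G>A"),
    (9825, "G>A"),
    (9896, "T>C"),
    (13708, "C>T"),
    (14977, "T>C"),
    (15524, "C>T"),
    (15526, "C>T"),
    (16660, "T>C"),
    (16663, "C>T"),
    (16671, "T>C"),
]

# --- conservative-somatic exclusions ---
EXCLUDED_CLADES = (3,)            # clades too mutation-poor to rule out multiple origins
TRUNK_GROUP_PREFIXES = ("CTVT_1A", "CTVT_1B1", "CTVT_2A")
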