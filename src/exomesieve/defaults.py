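"""Single source of truth for the analysis thresholds.

Every tunable cutoff used across the pipeline lives here so that a run is
described by one coherent set of constants.  Modules take these as keyword
defaults; overriding them per call is always possible.
"""

# Splice-region window: intronic variants within this many bases of a splice
# site are retained by the transcript-effect filter.
MAX_SPLICE_DISTANCE = 20

# Founder-frequency rarity: a variant is "common" when the lower bound of the
# 95% Wilson interval of its founder MAF exceeds this proportion.
RARITY_MAF_THRESHOLD = 0.01
WILSON_CONFIDENCE = 0.95

# Per-chromosome-class alt-allele count cutoffs that reproduce the study's
# printed rule (>=6 autosomal, >=5 X, >=2 Y alleles => too common).
RARITY_COUNT_CUTOFFS = {"autosomal": 6, "X": 5, "Y": 2}

# Read-depth thresholds (reads) used throughout the coverage analysis.
DEPTH_THRESHOLDS = (10, 20)
LOW_DEPTH_THRESHOLD = 10

# A gene is flagged when more than this fraction of its exons is consistently
# low across every sample (strict inequality).
GENE_LOW_EXON_FRACTION = 0.25

# Capture-target flank (bases) for medium-indel on/off-target classification.
TARGET_FLANK = 50

# Non-exonic variants: distance cutoff (bases) used for the "near exon"
# cumulative fraction, matching the sequencing-library insert footprint.
NEAR_EXON_CUTOFF = 500

# Deleteriousness tiers on the Phred-like scale (inclusive thresholds).
PHRED_TIERS = (10, 15, 20)

# Positional fallback policy for matching structural-variant calls when
# inserted sequence is unavailable.
SV_POSITION_TOLERANCE = 10
SV_SIZE_RATIO = 0.8

EFFECT_CLASSES_KEPT = frozenset(
    {
        "non_synonymous",
        "start_gain_loss",
        "stop_gain_loss",
        "frameshift",
        "canonical_splice",
        "intronic_near_splice",
    }
)
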