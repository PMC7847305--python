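"""Canonical analysis constants, each traceable to the published criteria.

Every decision threshold used anywhere in the package lives here so that a
pipeline run can log exactly one set of numbers.
"""

# --- expansion-microscopy synapse criteria (post-expansion micrometres) ---
THETA_SIDE_UM = 0.95       # side-plane overlap above which an apposition is a synapse
THETA_FACE_UM = 1.75       # face-view (z-stack) overlap threshold
MIN_BOUTON_DIAMETER_UM = 0.4
PROFILE_LEVEL = 0.5        # half-max level at which overlap is read off profiles
FACE_BOX_UM = 2.0          # side of the square box used for face-view z profiles
CLOSE_CONTACT_GAP_UM = 1.0  # close-nonsynaptic vs separate cut (post-expansion)
ORIENTATION_CONE_DEG = 45.0  # half-angle about z separating face from side views
CONFOCAL_MAX_GAP_VOXELS = 1  # "no dark pixels" rule for confocal close appositions
DEFAULT_EXPANSION_FACTOR = 4.17  # 250 um imaged / 60 um pre-expansion

# --- calcium responder calling ---
DRIFT_LIMIT_PCT = 5.0      # recordings with >=5% baseline drift are rejected
THRESHOLD_N_SD = 2.0       # responder threshold = control mean + 2 SD
ACSF_ARTIFACT_MEAN_PCT = 4.5
ACSF_ARTIFACT_SD_PCT = 0.5

# --- photometry / LH ---
SE_FRACTION_OF_MAX = 0.10  # synchronization events exceed 10% of recording max
SE_ABRUPTNESS_S = 120.0    # rise from 10%-of-max to peak within 2 min
SE_REFRACTORY_S = 60.0     # peaks closer than this are merged
LH_ASSAY_FLOOR_NG_ML = 0.04
LH_ASSAY_CV = 0.093
COINCIDENCE_WINDOW_MIN = 10.0
PHOTOMETRY_SCHEDULE_S = (5.0, 15.0)  # scheduled acquisition: 5 s on, 15 s off
BASELINE_PERCENTILE = 10.0  # running-baseline percentile for dF/F
BASELINE_WINDOW_S = 1800.0  # running-baseline window (30 min)
OUTLAST_MIN_FRAMES = 2     # consecutive post-puff frames above threshold
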