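"""Published benchmark rows bundled as worked-example inputs.

``TRACKING_ROWS`` holds per-dataset tracking results for five classical
trackers (a centroid Kalman tracker, SORT, DeepSORT, an optical-flow
tracker, and a detector-regression tracker) on four multi-object tracking
benchmarks: DanceTrack, SportsMOT, MOT17 and a handball practice-session
recording.  They are the standard worked example for
:func:`skelsuite.mot_metrics.aggregate_reports` — averaging a tracker's
rows across datasets yields its cross-dataset summary row.

``POSE_RIHJS_BASE`` / ``POSE_RIHJS_RETRAINED`` hold PA-PCK@0.15 (%) and
PA-MPJPE (height-normalized units) for two-stage 3D pose pipelines on a
handball jump-shot dataset, before and after the 2D stage was fine-tuned
on that domain.  Each entry is (base value, delta after Kalman smoothing,
delta after smoothing + retargeting); deltas are relative to the base
column.  Differencing retrained against base pipelines gives the average
benefit of in-domain fine-tuning.
"""

TRACKING_METRICS = ("MOTA", "MOTP", "IDF1", "IDsw", "Recall", "Precision", "MT", "ML")

TRACKING_DATASETS = ("DanceTrack", "SportsMOT", "MOT17", "RI-HB-PT")

#: {tracker: {dataset: {metric: value}}}
TRACKING_ROWS = {
    "CentroidKF": {
        "DanceTrack": dict(MOTA=76.9, MOTP=0.201, IDF1=7.9, IDsw=47550,
                           Recall=95.3, Precision=95.3, MT=409, ML=0),
        "SportsMOT": dict(MOTA=15.4, MOTP=0.247, IDF1=5.9, IDsw=43469,
                          Recall=64.7, Precision=64.7, MT=133, ML=0),
        "MOT17": dict(MOTA=60.7, MOTP=0.140, IDF1=49.0, IDsw=11200,
                      Recall=83.1, Precision=83.1, MT=366, ML=26),
        "RI-HB-PT": dict(MOTA=69.4, MOTP=0.231, IDF1=19.3, IDsw=9912,
                         Recall=87.0, Precision=87.0, MT=310, ML=15),
    },
    "SORT": {
        "DanceTrack": dict(MOTA=27.5, MOTP=0.313, IDF1=11.7, IDsw=16052,
                           Recall=66.1, Precision=66.1, MT=20, ML=0),
        "SportsMOT": dict(MOTA=15.6, MOTP=0.254, IDF1=6.2, IDsw=48186,
                          Recall=65.5, Precision=65.5, MT=4, ML=0),
        "MOT17": dict(MOTA=56.5, MOTP=0.159, IDF1=52.4, IDsw=9909,
                      Recall=80.7, Precision=80.7, MT=220, ML=2),
        "RI-HB-PT": dict(MOTA=49.0, MOTP=0.261, IDF1=21.4, IDsw=6299,
                         Recall=76.0, Precision=76.0, MT=225, ML=16),
    },
    "DeepSORT": {
        "DanceTrack": dict(MOTA=68.0, MOTP=0.160, IDF1=43.0, IDsw=4717,
                           Recall=97.6, Precision=77.5, MT=418, ML=0),
        "SportsMOT": dict(MOTA=79.9, MOTP=0.149, IDF1=63.7, IDsw=2939,
                          Recall=99.2, Precision=84.4, MT=635, ML=0),
        "MOT17": dict(MOTA=71.0, MOTP=0.062, IDF1=70.9, IDsw=1159,
                      Recall=90.5, Precision=90.5, MT=664, ML=24),
        "RI-HB-PT": dict(MOTA=70.2, MOTP=0.063, IDF1=38.7, IDsw=2276,
                         Recall=99.7, Precision=77.8, MT=353, ML=4),
    },
    "FlowTracker": {
        "DanceTrack": dict(MOTA=38.1, MOTP=0.262, IDF1=13.5, IDsw=10448,
                           Recall=66.4, Precision=72.4, MT=59, ML=1),
        "SportsMOT": dict(MOTA=25.4, MOTP=0.281, IDF1=12.2, IDsw=9873,
                          Recall=62.6, Precision=64.7, MT=16, ML=3),
        "MOT17": dict(MOTA=37.1, MOTP=0.156, IDF1=38.2, IDsw=2093,
                      Recall=47.4, Precision=83.6, MT=162, ML=310),
        "RI-HB-PT": dict(MOTA=68.0, MOTP=0.222, IDF1=16.6, IDsw=3770,
                         Recall=84.6, Precision=85.1, MT=125, ML=145),
    },
    "Tracktor++": {
        "DanceTrack": dict(MOTA=67.4, MOTP=0.262, IDF1=29.4, IDsw=18255,
                           Recall=75.1, Precision=96.9, MT=166, ML=0),
        "SportsMOT": dict(MOTA=64.6, MOTP=0.297, IDF1=42.9, IDsw=7949,
                          Recall=78.0, Precision=89.8, MT=298, ML=0),
        "MOT17": dict(MOTA=64.8, MOTP=0.258, IDF1=64.8, IDsw=3263,
                      Recall=73.4, Precision=91.3, MT=356, ML=115),
        "RI-HB-PT": dict(MOTA=92.4, MOTP=0.202, IDF1=49.6, IDsw=1346,
                         Recall=94.8, Precision=98.1, MT=176, ML=137),
    },
}

#: {pipeline: {"pck": (base, +KSM delta, +KSM+RET delta),
#:             "mpjpe": (base, +KSM delta, +KSM+RET delta)}}
POSE_RIHJS_BASE = {
    "MaskRCNN+GnTCN": {"pck": (84.545, 0.771, 1.135),
                       "mpjpe": (0.098, -0.002, -0.005)},
    "MaskRCNN+EvoSkeleton": {"pck": (86.485, 2.132, 2.415),
                             "mpjpe": (0.094, -0.006, -0.010)},
    "MaskRCNN+VideoPose3D": {"pck": (73.718, -0.152, 3.084),
                             "mpjpe": (0.124, 0.000, -0.008)},
    "UDP-Pose+GnTCN": {"pck": (90.797, 0.551, 1.370),
                       "mpjpe": (0.083, -0.001, -0.004)},
    "UDP-Pose+EvoSkeleton": {"pck": (94.436, 0.695, 1.009),
                             "mpjpe": (0.074, -0.002, -0.005)},
    "UDP-Pose+VideoPose3D": {"pck": (76.357, -0.232, 2.916),
                             "mpjpe": (0.117, -0.000, -0.007)},
}

POSE_RIHJS_RETRAINED = {
    "MaskRCNN+GnTCN": {"pck": (87.574, 0.644, 0.970),
                       "mpjpe": (0.090, -0.002, -0.004)},
    "MaskRCNN+EvoSkeleton": {"pck": (89.562, 1.875, 2.004),
                             "mpjpe": (0.086, -0.006, -0.009)},
    "MaskRCNN+VideoPose3D": {"pck": (76.970, -0.196, 2.258),
                             "mpjpe": (0.118, 0.000, -0.007)},
    "UDP-Pose+GnTCN": {"pck": (92.205, 0.486, 0.974),
                       "mpjpe": (0.080, -0.001, -0.003)},
    "UDP-Pose+EvoSkeleton": {"pck": (94.462, 0.537, 0.303),
                             "mpjpe": (0.073, -0.002, -0.003)},
    "UDP-Pose+VideoPose3D": {"pck": (78.122, -0.267, 2.053),
                             "mpjpe": (0.115, -0.000, -0.006)},
}


def retraining_gain(stage: str, metric: str) -> float:
    """Average base-column gain of fine-tuning the given 2D stage.

    ``stage`` is ``"MaskRCNN"`` or ``"UDP-Pose"``; ``metric`` ``"pck"``
    (gain = retrained − base) or ``"mpjpe"`` (gain = base − retrained,
    positive = error reduced).  Truncated at the printed precision
    (2 decimals for PCK, 3 for MPJPE).
    """
    diffs = []
    for name, row in POSE_RIHJS_RETRAINED.items():
        if not name.startswith(stage):
            continue
        base = POSE_RIHJS_BASE[name][metric][0]
        new = row[metric][0]
        diffs.append(new - base if metric == "pck" else base - new)
    mean = sum(diffs) / len(diffs)
    decimals = 2 if metric == "pck" else 3
    scaled = round(mean * 10 ** decimals, 6)
    return int(scaled) / 10 ** decimals
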