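"""Empirical amino-acid exchangeability data (lower-triangular) and frequencies.

Residue order: A R N D C Q E G H I L K M F P S T W Y V.
"""

WAG_LOWER = [
    [0.551571],
    [0.509848, 0.635346],
    [0.738998, 0.147304, 5.42942],
    [1.02704, 0.528191, 0.265256, 0.0302949],
    [0.908598, 3.0355, 1.54364, 0.616783, 0.0988179],
    [1.58285, 0.439157, 0.947198, 6.17416, 0.021352, 5.46947],
    [1.41672, 0.584665, 1.12556, 0.865584, 0.306674, 0.330052, 0.567717],
    [0.316954, 2.13715, 3.95629, 0.930676, 0.248972, 4.29411, 0.570025, 0.24941],
    [0.193335, 0.186979, 0.554236, 0.039437, 0.170135, 0.113917, 0.127395, 0.0304501, 0.13819],
    [0.397915, 0.497671, 0.131528, 0.0848047, 0.384287, 0.869489, 0.154263, 0.0613037, 0.499462, 3.17097],
    [0.906265, 5.35142, 3.01201, 0.479855, 0.0740339, 3.8949, 2.58443, 0.373558, 0.890432, 0.323832, 0.257555],
    [0.893496, 0.683162, 0.198221, 0.103754, 0.390482, 1.54526, 0.315124, 0.1741, 0.404141, 4.25746, 4.85402, 0.934276],
    [0.210494, 0.102711, 0.0961621, 0.0467304, 0.39802, 0.0999208, 0.0811339, 0.049931, 0.679371, 1.05947, 2.11517, 0.088836, 1.19063],
    [1.43855, 0.679489, 0.195081, 0.423984, 0.109404, 0.933372, 0.682355, 0.24357, 0.696198, 0.0999288, 0.415844, 0.556896, 0.171329, 0.161444],
    [3.37079, 1.22419, 3.97423, 1.07176, 1.40766, 1.02887, 0.704939, 1.34182, 0.740169, 0.31944, 0.344739, 0.96713, 0.493905, 0.545931, 1.61328],
    [2.12111, 0.554413, 2.03006, 0.374866, 0.512984, 0.857928, 0.822765, 0.225833, 0.473307, 1.45816, 0.326622, 1.38698, 1.51612, 0.171903, 0.795384, 4.37802],
    [0.113133, 1.16392, 0.0719167, 0.129767, 0.71707, 0.215737, 0.156557, 0.336983, 0.262569, 0.212483, 0.665309, 0.137505, 0.515706, 1.52964, 0.139405, 0.523742, 0.110864],
    [0.240735, 0.381533, 1.086, 0.325711, 0.543833, 0.22771, 0.196303, 0.103604, 3.87344, 0.42017, 0.398618, 0.133264, 0.428437, 6.45428, 0.216046, 0.786993, 0.291148, 2.48539],
    [2.00601, 0.251849, 0.196246, 0.152335, 1.00214, 0.301281, 0.588731, 0.187247, 0.118358, 7.8213, 1.80034, 0.305434, 2.05845, 0.649892, 0.314887, 0.232739, 1.38823, 0.365369, 0.31473],
]

WAG_FREQS = [
    0.08662790866279087, 0.04397200439720044, 0.0390894039089404, 0.057045105704510574, 0.019307801930780195,
    0.03672810367281037, 0.05805890580589058, 0.08325180832518084, 0.024431302443130246, 0.04846600484660049,
    0.08620900862090086, 0.062028606202860624, 0.019502701950270197, 0.03843190384319038, 0.045763104576310464,
    0.06951790695179069, 0.06101270610127062, 0.014385901438590145, 0.035274203527420354, 0.07089560708956072,
]

LG_LOWER = [
    [0.425093],
    [0.276818, 0.751878],
    [0.395144, 0.123954, 5.076149],
    [2.489084, 0.534551, 0.528768, 0.062556],
    [0.969894, 2.807908, 1.695752, 0.523386, 0.084808],
    [1.038545, 0.36397, 0.541712, 5.24387, 0.003499, 4.128591],
    [2.06604, 0.390192, 1.437645, 0.844926, 0.569265, 0.267959, 0.348847],
    [0.358858, 2.426601, 4.509238, 0.927114, 0.640543, 4.813505, 0.423881, 0.311484],
    [0.14983, 0.126991, 0.191503, 0.01069, 0.320627, 0.072854, 0.044265, 0.008705, 0.108882],
    [0.395337, 0.301848, 0.068427, 0.015076, 0.594007, 0.582457, 0.069673, 0.044261, 0.366317, 4.145067],
    [0.536518, 6.326067, 2.145078, 0.282959, 0.013266, 3.234294, 1.807177, 0.296636, 0.697264, 0.159069, 0.1375],
    [1.124035, 0.484133, 0.371004, 0.025548, 0.89368, 1.672569, 0.173735, 0.139538, 0.442472, 4.273607, 6.312358, 0.656604],
    [0.253701, 0.052722, 0.089525, 0.017416, 1.105251, 0.035855, 0.018811, 0.089586, 0.682139, 1.112727, 2.592692, 0.023918, 1.798853],
    [1.177651, 0.332533, 0.161787, 0.394456, 0.075382, 0.624294, 0.419409, 0.196961, 0.508851, 0.078281, 0.24906, 0.390322, 0.099849, 0.094464],
    [4.727182, 0.858151, 4.008358, 1.240275, 2.784478, 1.223828, 0.611973, 1.73999, 0.990012, 0.064105, 0.182287, 0.748683, 0.34696, 0.361819, 1.338132],
    [2.139501, 0.578987, 2.000679, 0.42586, 1.14348, 1.080136, 0.604545, 0.129836, 0.584262, 1.033739, 0.302936, 1.136863, 2.020366, 0.165001, 0.571468, 6.472279],
    [0.180717, 0.593607, 0.045376, 0.02989, 0.670128, 0.236199, 0.077852, 0.268491, 0.597054, 0.11166, 0.619632, 0.049906, 0.696175, 2.457121, 0.095131, 0.248862, 0.140825],
    [0.218959, 0.31444, 0.612025, 0.135107, 1.165532, 0.257336, 0.120037, 0.054679, 5.306834, 0.232523, 0.299648, 0.131932, 0.481306, 7.803902, 0.089613, 0.400547, 0.245841, 3.151815],
    [2.54787, 0.170887, 0.083688, 0.037967, 1.959291, 0.210332, 0.245034, 0.076701, 0.119013, 10.649107, 1.702745, 0.185202, 1.898718, 0.654683, 0.296501, 0.098369, 2.188158, 0.18951, 0.249313],
]

LG_FREQS = [
    0.07906592093407908, 0.05594094405905594, 0.04197695802304198, 0.053051946948053055, 0.012936987063012939,
    0.040766959233040766, 0.07158592841407159, 0.05733694266305734, 0.022354977645022357, 0.06215693784306216,
    0.09908090091909909, 0.0645999354000646, 0.022950977049022953, 0.042301957698042306, 0.04403995596004404,
    0.0611969388030612, 0.05328694671305329, 0.012065987934012068, 0.034154965845034156, 0.06914693085306915,
]
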