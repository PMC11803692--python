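"""Diffusion gradient direction sets.

DIRECTIONS_30: unit vectors distributed by antipodal electrostatic repulsion
(Coulomb energy minimization on the sphere, deterministic optimization,
frozen here). Design-matrix condition number for the 6-component tensor fit
is ~1.59, i.e. well conditioned.
"""

import numpy as np

DIRECTIONS_30 = np.array([
    (0.080890345419315, -0.713506813220912, 0.695963202694857),
    (0.263748632620807, -0.784529626861289, -0.561203994432988),
    (-0.039734744943699, -0.973343945106057, 0.225882081116757),
    (-0.567588922607650, 0.444780421077705, 0.692829843438507),
    (0.065317961757160, 0.961265172242903, 0.267773845819026),
    (-0.270059163129824, 0.310623467220613, -0.911362227668814),
    (0.962877011475606, 0.205806630066559, -0.174675389773295),
    (-0.370883460350186, 0.860084443318832, -0.350285896375529),
    (-0.693993657945236, -0.334851658661915, 0.637375218708066),
    (0.664945665042820, 0.404252404227086, 0.628034438719234),
    (0.853809550649356, -0.114770021005460, -0.507776617715262),
    (-0.503938282024718, 0.016053950472537, 0.863590457673196),
    (0.059916174738086, 0.026812536012466, -0.997843244160793),
    (0.482451617558255, 0.778731468723849, 0.401020867704688),
    (-0.963974974402572, 0.257100983960568, 0.068200680143738),
    (0.363249308290612, 0.762819398089878, -0.534935983014966),
    (0.939194504384258, 0.137807881820032, 0.314519746029854),
    (0.384005886277620, -0.915405669807482, -0.120714286596304),
    (-0.455240610663689, -0.888918502524845, 0.050792541495168),
    (0.554714382064793, -0.539251687660623, 0.633639938518434),
    (-0.739083355342259, -0.607794491224869, 0.290416339576014),
    (0.325623619758911, 0.237043466048426, 0.915303039139963),
    (-0.264437298359801, -0.432716139650003, 0.861875662565412),
    (-0.191115633524148, -0.669808084006865, -0.717517905854423),
    (-0.724741677002081, 0.613477881784620, 0.313678800968867),
    (0.737024453510405, -0.660684573963702, 0.142445949939232),
    (0.660859433556010, -0.055202127284638, 0.748476809409136),
    (-0.815889124855529, -0.553900913832994, -0.165887653541344),
    (-0.870456522017721, 0.293034760802524, -0.395520002323803),
    (-0.149043749703922, 0.418883582201465, 0.895724569963481),
])
DIRECTIONS_30 /= np.linalg.norm(DIRECTIONS_30, axis=1, keepdims=True)
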