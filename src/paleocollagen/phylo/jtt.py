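"""Published JTT amino-acid replacement model constants.

Exchangeabilities (symmetric, arbitrary scale) and stationary frequencies of
the Jones-Taylor-Thornton (1992) empirical matrix, in the conventional
ARNDCQEGHILKMFPSTWYV residue order used by most phylogenetics software.
"""

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower triangle of the symmetric exchangeability matrix, column-major,
# i.e. S[1,0], S[2,0], ..., S[19,0], S[2,1], ... in AA_ORDER indexing.
_LOWER_TRIANGLE = [
    58.0, 54.0, 81.0, 56.0, 57.0, 105.0, 179.0, 27.0, 36.0, 30.0,
    35.0, 54.0, 15.0, 194.0, 378.0, 475.0, 9.0, 11.0, 298.0, 45.0,
    16.0, 113.0, 310.0, 29.0, 137.0, 328.0, 22.0, 38.0, 646.0, 44.0,
    5.0, 74.0, 101.0, 64.0, 126.0, 20.0, 17.0, 528.0, 34.0, 86.0,
    58.0, 81.0, 391.0, 47.0, 12.0, 263.0, 30.0, 10.0, 15.0, 503.0,
    232.0, 8.0, 70.0, 16.0, 10.0, 49.0, 767.0, 130.0, 112.0, 11.0,
    7.0, 26.0, 15.0, 4.0, 15.0, 59.0, 38.0, 4.0, 46.0, 31.0,
    9.0, 5.0, 59.0, 69.0, 17.0, 23.0, 7.0, 31.0, 78.0, 14.0,
    223.0, 42.0, 115.0, 209.0, 62.0, 323.0, 26.0, 597.0, 9.0, 72.0,
    292.0, 43.0, 4.0, 164.0, 53.0, 51.0, 18.0, 24.0, 20.0, 119.0,
    26.0, 12.0, 9.0, 181.0, 18.0, 5.0, 18.0, 30.0, 32.0, 10.0,
    7.0, 45.0, 23.0, 6.0, 6.0, 27.0, 14.0, 5.0, 24.0, 201.0,
    33.0, 55.0, 8.0, 47.0, 16.0, 56.0, 45.0, 33.0, 40.0, 115.0,
    73.0, 46.0, 8.0, 573.0, 11.0, 229.0, 21.0, 479.0, 89.0, 10.0,
    40.0, 245.0, 9.0, 32.0, 961.0, 14.0, 388.0, 248.0, 102.0, 59.0,
    25.0, 52.0, 24.0, 180.0, 65.0, 4.0, 21.0, 47.0, 103.0, 10.0,
    8.0, 14.0, 43.0, 16.0, 29.0, 226.0, 24.0, 18.0, 323.0, 17.0,
    92.0, 12.0, 53.0, 536.0, 62.0, 285.0, 118.0, 6.0, 10.0, 23.0,
    477.0, 35.0, 63.0, 38.0, 12.0, 21.0, 112.0, 71.0, 25.0, 16.0,
]

JTT_FREQUENCIES = np.array([
    0.076747923252076758, 0.051690948309051694, 0.042644957355042652, 0.051543948456051550,
    0.019802980197019805, 0.040751959248040752, 0.061829938170061841, 0.073151926848073159,
    0.022943977056022944, 0.053760946239053767, 0.091903908096091905, 0.058675941324058678,
    0.023825976174023829, 0.040125959874040135, 0.050900949099050907, 0.068764931235068771,
    0.058564941435058568, 0.014260985739014262, 0.032101967898032102, 0.066004933995066004,
])


def exchangeability_matrix() -> np.ndarray:
    """Return the symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    idx = [(i, j) for j in range(20) for i in range(j + 1, 20)]
    for (i, j), v in zip(idx, _LOWER_TRIANGLE):
        s[i, j] = v
        s[j, i] = v
    return s

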