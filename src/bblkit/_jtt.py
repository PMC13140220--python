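"""JTT (Jones-Taylor-Thornton 1992) empirical amino-acid replacement model data.

Lower-triangle exchangeabilities and stationary frequencies in the order
A R N D C Q E G H I L K M F P S T W Y V (the conventional integer-scaled
values used by phylogenetics software).
"""

import numpy as np

JTT_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Row-wise lower triangle: row i (i=1..19) holds entries for pairs (i, 0..i-1).
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9, 11,
    298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126,
    20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232, 8, 70,
    16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5,
    59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26, 597, 9, 72,
    292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18, 5, 18, 30,
    32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47, 16, 56, 45, 33,
    40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40, 245, 9, 32, 961, 14,
    388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16,
    29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477,
    35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()


def jtt_exchangeabilities() -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    return s
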