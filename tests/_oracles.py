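"""Independent brute-force oracles, coded with plain Python loops.

These deliberately avoid numpy vectorization and share no code with the
package: each metric is a direct transliteration of its defining sums, used
to cross-check the implementation path.
"""

import cmath
import math


def coherence_direct(x, y):
    s = 0 + 0j
    px = py = 0.0
    for xi, yi in zip(x, y):
        s += xi * yi.conjugate()
        px += abs(xi) ** 2
        py += abs(yi) ** 2
    return abs(s) / math.sqrt(px * py)


def imaginary_coherence_direct(x, y):
    s = 0 + 0j
    px = py = 0.0
    for xi, yi in zip(x, y):
        s += xi * yi.conjugate()
        px += abs(xi) ** 2
        py += abs(yi) ** 2
    return abs(s.imag) / math.sqrt(px * py)


def _pearson_direct(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    va = sum((ai - ma) ** 2 for ai in a)
    vb = sum((bi - mb) ** 2 for bi in b)
    return num / math.sqrt(va * vb)


def envelope_correlation_direct(x, y):
    return _pearson_direct([abs(v) for v in x], [abs(v) for v in y])


def power_correlation_direct(x, y):
    return _pearson_direct([abs(v) ** 2 for v in x], [abs(v) ** 2 for v in y])


def plv_direct(x, y):
    n = 0
    s = 0 + 0j
    for xi, yi in zip(x, y):
        if abs(xi) > 0 and abs(yi) > 0:
            s += (xi / abs(xi)) * (yi / abs(yi)).conjugate()
            n += 1
    return abs(s) / n


def circular_mean_direct(angles):
    return cmath.phase(sum(cmath.exp(1j * a) for a in angles))


def ccorr_direct(x, y):
    tx = [cmath.phase(v) for v in x]
    ty = [cmath.phase(v) for v in y]
    mx = circular_mean_direct(tx)
    my = circular_mean_direct(ty)
    sx = [math.sin(t - mx) for t in tx]
    sy = [math.sin(t - my) for t in ty]
    num = sum(a * b for a, b in zip(sx, sy))
    vx = sum(a * a for a in sx)
    vy = sum(b * b for b in sy)
    return num / math.sqrt(vx * vy)


DIRECT = {
    "coherence": coherence_direct,
    "imaginary_coherence": imaginary_coherence_direct,
    "envelope_correlation": envelope_correlation_direct,
    "power_correlation": power_correlation_direct,
    "plv": plv_direct,
    "ccorr": ccorr_direct,
}
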