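"""Independent direct-summation oracle for the agreement statistics.

Pure-Python loops, no numpy vectorization and no calls into the package's
statistics code, so that agreement between the two routes is meaningful.
"""

import math


def oracle_pearson_r(reference, test):
    n = len(reference)
    mx = sum(reference) / n
    my = sum(test) / n
    sxy = sxx = syy = 0.0
    for x, y in zip(reference, test):
        sxy += (x - mx) * (y - my)
        sxx += (x - mx) ** 2
        syy += (y - my) ** 2
    return sxy / math.sqrt(sxx * syy)


def oracle_bland_altman(reference, test):
    n = len(reference)
    diffs = [x - y for x, y in zip(reference, test)]
    bias = sum(diffs) / n
    var = sum((d - bias) ** 2 for d in diffs) / (n - 1)
    sd = math.sqrt(var)
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def oracle_relative_errors(reference, test):
    return [100.0 * (y - x) / x for x, y in zip(reference, test)]


def oracle_mare(reference, test):
    errors = oracle_relative_errors(reference, test)
    return sum(abs(e) for e in errors) / len(errors)
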