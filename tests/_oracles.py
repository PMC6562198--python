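"""Independent brute-force oracles, written as literal if/else transcriptions
of the score charts (deliberately not sharing any code with the package)."""


def news_weight(component, value):
    if component == "respiratory_rate":
        if value < 9:
            return 3
        elif value < 12:
            return 1
        elif value < 21:
            return 0
        elif value < 25:
            return 2
        else:
            return 3
    if component == "spo2":
        if value < 92:
            return 3
        elif value < 94:
            return 2
        elif value < 96:
            return 1
        else:
            return 0
    if component == "temperature":
        v = round(value, 1)
        if v < 35.1:
            return 3
        elif v < 36.1:
            return 1
        elif v < 38.1:
            return 0
        elif v < 39.1:
            return 1
        else:
            return 2
    if component == "systolic_bp":
        if value < 91:
            return 3
        elif value < 101:
            return 2
        elif value < 111:
            return 1
        elif value < 220:
            return 0
        else:
            return 3
    if component == "heart_rate":
        if value < 41:
            return 3
        elif value < 51:
            return 1
        elif value < 91:
            return 0
        elif value < 111:
            return 1
        elif value < 131:
            return 2
        else:
            return 3
    if component == "supplemental_oxygen":
        return 2 if value else 0
    if component == "consciousness":
        return 0 if value == "A" else 3
    raise KeyError(component)


def news_aggregate(hr, sbp, rr, temp, spo2, oxygen, avpu):
    return (
        news_weight("heart_rate", hr)
        + news_weight("systolic_bp", sbp)
        + news_weight("respiratory_rate", rr)
        + news_weight("temperature", temp)
        + news_weight("spo2", spo2)
        + news_weight("supplemental_oxygen", oxygen)
        + news_weight("consciousness", avpu)
    )


def ldtews_weight(analyte, value, sex=None):
    if value is None:
        return 0
    if analyte == "albumin":
        if value < 18:
            return 3
        elif value < 27:
            return 2
        elif value < 34:
            return 1
        return 0
    if analyte == "creatinine":
        lo, hi = (110, 200) if sex == "male" else (90, 170)
        if value < lo:
            return 0
        elif value < hi:
            return 1
        return 2
    if analyte == "haemoglobin":
        lo, hi = (100, 180) if sex == "male" else (95, 165)
        if value < lo:
            return 1
        elif value < hi:
            return 0
        return 1
    if analyte == "potassium":
        if value < 2.9:
            return 2
        elif value < 3.4:
            return 1
        elif value < 5.5:
            return 0
        elif value < 6.0:
            return 1
        return 2
    if analyte == "sodium":
        if value < 126:
            return 2
        elif value < 133:
            return 1
        elif value < 146:
            return 0
        elif value < 152:
            return 1
        return 2
    if analyte == "urea":
        if value < 7.5:
            return 0
        elif value < 14:
            return 1
        elif value < 23:
            return 2
        return 3
    if analyte == "wcc":
        if value < 2:
            return 2
        elif value < 4:
            return 1
        elif value < 12:
            return 0
        elif value < 20:
            return 1
        return 2
    raise KeyError(analyte)


def pairwise_auc(scores, labels):
    """O(n^2) concordance: P(s+ > s-) + 0.5 P(equal) over all pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
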