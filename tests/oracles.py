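"""Independent brute-force oracles: plain pair enumeration, no package code."""


def brute_density(values, directed):
    n = len(values)
    ties = 0
    possible = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if directed:
                possible += 1
                ties += 1 if values[i][j] else 0
            elif i < j:
                possible += 1
                ties += 1 if values[i][j] else 0
    return ties / possible


def brute_degrees(values, directed, basis):
    n = len(values)
    out = []
    for i in range(n):
        if basis == "in":
            out.append(sum(1 for j in range(n) if j != i and values[j][i]))
        elif basis == "out":
            out.append(sum(1 for j in range(n) if j != i and values[i][j]))
        else:
            if directed:
                out.append(
                    sum(1 for j in range(n) if j != i and (values[i][j] or values[j][i]))
                )
            else:
                out.append(sum(1 for j in range(n) if j != i and values[i][j]))
    return out


def brute_centralization(values, directed, basis):
    n = len(values)
    degs = brute_degrees(values, directed, basis)
    cmax = max(degs)
    if cmax == 0:
        return 0.0
    gap_sum = sum(cmax - d for d in degs)
    denom = (n - 1) * (n - 2) if basis == "total" else (n - 1) ** 2
    return gap_sum / denom
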