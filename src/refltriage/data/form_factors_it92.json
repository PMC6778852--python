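{
  "comment": "4-Gaussian X-ray scattering-factor coefficients f0(s) = sum a_i exp(-b_i s^2) + c with s^2 = (sin(theta)/lambda)^2 = 1/(4 d^2). International Tables vol. C parameterization.",
  "H": {"a": [0.489918, 0.262003, 0.196767, 0.049879],
        "b": [20.6593, 7.74039, 49.5519, 2.20159],
        "c": 0.001305, "z": 1},
  "C": {"a": [2.31, 1.02, 1.5886, 0.865],
        "b": [20.8439, 10.2075, 0.5687, 51.6512],
        "c": 0.2156, "z": 6},
  "N": {"a": [12.2126, 3.1322, 2.0125, 1.1663],
        "b": [0.0057, 9.8933, 28.9975, 0.5826],
        "c": -11.529, "z": 7},
  "O": {"a": [3.0485, 2.2868, 1.5463, 0.867],
        "b": [13.2771, 5.7011, 0.3239, 32.9089],
        "c": 0.2508, "z": 8},
  "P": {"a": [6.4345, 4.1791, 1.78, 1.4908],
        "b": [1.9067, 27.157, 0.526, 68.1645],
        "c": 1.1149, "z": 15},
  "S": {"a": [6.9053, 5.2034, 1.4379, 1.5863],
        "b": [1.4679, 22.2151, 0.2536, 56.172],
        "c": 0.8669, "z": 16}
}
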