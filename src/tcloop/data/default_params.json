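{
  "schema_version": "tcloop-params-1",
  "comment": "Canonical conductance-based defaults for the thalamocortical loop model. Membrane and kinetic constants follow the published Destexhe-family single-compartment models for cortical, thalamic relay (TC), reticular (TRN) and local interneuron (IN) cells; every value can be overridden via a config dict or user JSON.",
  "neurons": {
    "rodent": {
      "Ctx": {
        "Cm": 1.0,
        "g_leak": 0.1,
        "E_leak": -70.0,
        "g_Na": 50.0,
        "E_Na": 50.0,
        "g_K": 5.0,
        "E_K": -90.0,
        "V_T": -55.0
      },
      "TC": {
        "Cm": 1.0,
        "g_leak": 0.05,
        "E_leak": -70.0,
        "g_Na": 90.0,
        "E_Na": 50.0,
        "g_K": 10.0,
        "E_K": -95.0,
        "V_T": -52.0,
        "g_Ca": 3.0,
        "E_Ca": 120.0,
        "g_H": 0.04,
        "E_H": -43.0,
        "k2": 0.0004,
        "C": 0.0002
      },
      "TRN": {
        "Cm": 1.0,
        "g_leak": 0.05,
        "E_leak": -77.0,
        "g_Na": 100.0,
        "E_Na": 50.0,
        "g_K": 10.0,
        "E_K": -95.0,
        "V_T": -62.0,
        "g_Ca": 1.75,
        "E_Ca": 120.0
      }
    },
    "primate": {
      "Ctx": {
        "Cm": 1.0,
        "g_leak": 0.1,
        "E_leak": -70.0,
        "g_Na": 50.0,
        "E_Na": 50.0,
        "g_K": 5.0,
        "E_K": -90.0,
        "V_T": -55.0
      },
      "TC": {
        "Cm": 1.0,
        "g_leak": 0.05,
        "E_leak": -70.0,
        "g_Na": 90.0,
        "E_Na": 50.0,
        "g_K": 10.0,
        "E_K": -95.0,
        "V_T": -52.0,
        "g_Ca": 3.0,
        "E_Ca": 120.0,
        "g_H": 0.04,
        "E_H": -43.0,
        "k2": 0.0004,
        "C": 0.0002
      },
      "TRN": {
        "Cm": 1.0,
        "g_leak": 0.05,
        "E_leak": -77.0,
        "g_Na": 100.0,
        "E_Na": 50.0,
        "g_K": 10.0,
        "E_K": -95.0,
        "V_T": -62.0,
        "g_Ca": 1.75,
        "E_Ca": 120.0
      },
      "IN": {
        "Cm": 1.0,
        "g_leak": 0.1,
        "E_leak": -70.0,
        "g_Na": 50.0,
        "E_Na": 50.0,
        "g_K": 5.0,
        "E_K": -90.0,
        "V_T": -55.0
      }
    }
  },
  "synapses": {
    "AMPA": {
      "alpha": 1.1,
      "beta": 0.19,
      "E": 0.0
    },
    "NMDA": {
      "alpha": 0.072,
      "beta": 0.0066,
      "E": 0.0
    },
    "GABA_A": {
      "alpha": 5.0,
      "beta": 0.18,
      "E": -85.0
    },
    "GABA_B": {
      "K1": 1.3,
      "K2": 0.006,
      "K3": 0.09,
      "K4": 0.0064,
      "Kd": 100.0,
      "n": 4,
      "E": -95.0
    },
    "mGluR": {
      "K1": 1.3,
      "K2": 0.006,
      "K3": 0.09,
      "K4": 0.0064,
      "Kd": 100.0,
      "n": 4,
      "E": 0.0
    }
  },
  "transmitter": {
    "T_max": 1.0,
    "V_t": 2.0,
    "K_p": 5.0
  }
}
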