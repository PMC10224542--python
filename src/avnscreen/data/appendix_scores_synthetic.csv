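# Synthetic reconstruction of the per-compound external-predictor table.
# The proprietary calculators' outputs are not re-derivable; values here are
# stand-ins constrained to reproduce every figure printed in the study text
# (Table 1 rows, sub-collection sizes, top-3 rankings, flag sets).
code,GPCRL,ICHM,KI,NRL,PI,EI,osiris_clogp,osiris_logs,druglikeness,drug_score,tox_mutagenic,tox_tumorigenic,tox_irritant,tox_reproductive,leadlikeness,swissadme_druglikeness,pgp_substrate
1a,-0.20,-0.32,-0.26,0.05,-0.22,-0.02,1.20,-2.50,-2.60,0.25,none,none,none,medium,Y,Y,No
1p,-0.21,-0.33,-0.27,0.04,-0.23,-0.03,1.25,-2.55,-2.47,0.26,none,none,medium,none,Y,Y,No
1c,-0.11,-0.23,-0.19,0.12,-0.15,0.06,1.30,-2.60,-2.34,0.53,none,none,none,medium,Y,Y,No
1f,-0.23,-0.35,-0.29,0.02,-0.25,-0.05,1.35,-2.65,-2.21,0.28,none,none,medium,none,Y,Y,No
1s,-0.24,-0.36,-0.30,0.01,-0.26,-0.06,1.40,-2.70,-2.08,0.56,none,none,none,medium,Y,Y,No
2a,-0.10,-0.18,-0.14,0.08,-0.11,0.01,1.45,-2.75,-1.95,0.49,none,none,none,none,Y,Y,No
2p,-0.12,-0.20,-0.16,0.09,-0.13,0.04,1.50,-2.80,-1.82,0.55,none,none,none,none,Y,Y,No
2c,-0.10,-0.20,-0.15,0.17,-0.12,0.10,1.50,-2.60,-0.58,0.61,none,none,none,none,Y,Y,No
2f,-0.23,-0.35,-0.29,0.02,-0.25,-0.05,1.60,-2.90,-1.56,0.33,none,none,medium,none,Y,Y,No
2s,-0.24,-0.36,-0.30,0.01,-0.26,-0.06,1.65,-2.95,-1.43,0.34,none,none,none,medium,N,Y,No
2m,-0.20,-0.32,-0.26,0.05,-0.22,-0.02,1.70,-3.00,-1.30,0.55,none,none,medium,none,Y,Y,No
3a,-0.21,-0.33,-0.27,0.04,-0.23,-0.03,1.75,-3.05,-1.17,0.36,none,none,none,none,N,Y,No
3p,-0.22,-0.34,-0.28,0.03,-0.24,-0.04,1.80,-3.10,-1.04,0.37,none,none,none,none,N,Y,No
3c,-0.23,-0.35,-0.29,0.02,-0.25,-0.05,1.85,-3.15,-0.91,0.54,none,none,none,none,N,N,No
3f,-0.24,-0.36,-0.30,0.01,-0.26,-0.06,1.90,-3.20,-0.78,0.39,none,none,none,medium,N,Y,No
3h(1),-0.20,-0.32,-0.26,0.05,-0.22,-0.02,1.95,-3.25,-0.65,0.40,none,none,medium,none,N,Y,No
3h(2),-0.21,-0.33,-0.27,0.04,-0.23,-0.03,2.00,-3.30,-0.52,0.53,none,none,none,medium,N,Y,No
4p,-0.13,-0.21,-0.17,0.10,-0.12,0.03,2.05,-3.35,-0.39,0.54,none,none,none,none,Y,Y,No
4c,-0.12,-0.22,-0.18,0.11,-0.14,0.05,2.10,-3.40,-0.26,0.62,none,none,none,none,Y,Y,No
4f,-0.24,-0.36,-0.30,0.01,-0.26,-0.06,2.15,-3.45,-0.13,0.44,none,none,none,none,N,Y,No
5a,-0.20,-0.32,-0.26,0.05,-0.22,-0.02,2.20,-3.50,0.00,0.25,none,none,none,none,N,Y,No
5p,-0.21,-0.33,-0.27,0.04,-0.23,-0.03,2.25,-3.55,0.13,0.52,none,none,none,none,N,Y,No
5c,-0.22,-0.34,-0.28,0.03,-0.24,-0.04,2.30,-3.60,0.26,0.56,none,none,none,none,N,N,No
5f,-0.23,-0.35,-0.29,0.02,-0.25,-0.05,2.35,-3.65,0.39,0.28,none,none,medium,none,N,N,No
5s,-0.24,-0.36,-0.30,0.01,-0.26,-0.06,2.40,-3.70,0.52,0.29,none,none,none,medium,N,N,No
1pd,-0.20,-0.32,-0.26,0.05,-0.22,-0.02,2.45,-3.75,0.65,0.30,none,none,medium,none,Y,Y,No
1cd,0.12,-0.17,-0.13,-0.01,-0.10,0.04,2.50,-3.80,0.78,0.50,none,none,none,medium,Y,Y,No
1fd,-0.22,-0.34,-0.28,0.03,-0.24,-0.04,2.55,-3.85,0.91,0.32,none,none,medium,none,Y,Y,No
2ad,0.15,-0.15,-0.11,0.01,-0.08,0.07,2.60,-3.90,1.04,0.31,none,none,high,none,Y,Y,No
2pd,0.18,-0.13,-0.09,0.02,-0.06,0.08,2.00,-3.49,-1.15,0.52,none,none,none,none,Y,Y,No
2cd,0.18,-0.14,-0.08,0.05,-0.05,0.10,1.60,-3.23,-0.38,0.60,none,none,none,none,Y,Y,No
2fd,-0.21,-0.33,-0.27,0.04,-0.23,-0.03,2.75,-4.05,-2.47,0.57,none,none,none,none,N,Y,No
2sd,-0.22,-0.34,-0.28,0.03,-0.24,-0.04,2.80,-4.10,-2.34,0.53,none,none,none,none,N,Y,No
3pd,0.13,-0.16,-0.12,0.00,-0.09,0.05,2.85,-4.15,-2.21,0.48,none,none,none,none,Y,Y,No
3cd,-0.24,-0.36,-0.30,0.01,-0.26,-0.06,2.90,-4.20,-2.08,0.39,none,none,none,none,N,Y,No
3fd,-0.20,-0.32,-0.26,0.05,-0.22,-0.02,2.95,-4.25,-1.95,0.40,none,none,none,none,N,N,No
5pd,0.20,-0.16,-0.10,0.04,-0.03,0.09,3.00,-4.30,-1.82,0.47,none,none,none,none,Y,Y,No
5cd,-0.22,-0.34,-0.28,0.03,-0.24,-0.04,3.05,-4.35,-1.69,0.55,none,none,none,none,N,N,No
5fd,-0.23,-0.35,-0.29,0.02,-0.25,-0.05,3.10,-4.40,-1.56,0.43,none,none,none,none,N,N,No
Tranilast,-0.02,-0.26,-0.25,-0.15,-0.20,-0.08,2.74,-4.20,2.74,0.51,none,none,none,medium,Y,Y,No
dihydroavenanthramide D,-0.20,-0.32,-0.26,0.05,-0.22,-0.02,1.20,-2.50,-1.30,0.58,none,none,none,none,Y,Y,No
AVN A2,-0.21,-0.33,-0.27,0.04,-0.23,-0.03,1.25,-2.55,-1.17,0.58,none,none,none,none,N,Y,No
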