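[10, 20, 50, 100, 200, 500, 1000, 2000, 3070, 5000, 5040, 8128, 9197, 10000,
 10824, 15000, 15308, 17296, 20000, 25000, 30000, 35000, 40000, 45000, 50000,
 55000, 56885, 60000, 65000, 70000, 75000, 80000, 85000, 90000, 95000, 100000,
 110000, 120000]
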