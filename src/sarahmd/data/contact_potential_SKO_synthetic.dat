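# Synthetic stand-in contact-potential matrix ('SKO' slot).
# NOT the published table of that name: a deterministic surrogate
# with the additive-plus-hydrophobicity structure of knowledge-based
# contact potentials, for testing and demonstration. Supply the
# literature matrix in this same format to reproduce published scores.
A R N D C Q E G H I L K M F P S T W Y V
 -0.2098   0.2189   0.2310   0.1478  -0.2987   0.1827   0.1663  -0.0031   0.2034  -0.3661  -0.3025   0.1295  -0.1467  -0.2248   0.0028  -0.0462  -0.0865  -0.0428  -0.0450  -0.3649
  0.2189   0.3048   0.2258  -0.0112   0.1967   0.2121   0.0545   0.1926   0.1363   0.2266   0.2094   0.3967   0.2415   0.2404   0.1987   0.1858   0.2432   0.2006   0.1436   0.2337
  0.2310   0.2258   0.1585   0.1407   0.1833   0.1183   0.2422   0.1879   0.1474   0.1162   0.0311   0.1214   0.1841   0.1307   0.2439   0.1499   0.1840   0.1591   0.1020   0.1387
  0.1478  -0.0112   0.1407   0.3622   0.1217   0.2316   0.3735   0.1781   0.1402   0.1021   0.1230   0.0860   0.1630   0.1858   0.2656   0.1700   0.1822   0.1946   0.1817   0.1460
 -0.2987   0.1967   0.1833   0.1217  -0.4216   0.1079   0.1646  -0.0667   0.1585  -0.4674  -0.4864   0.1629  -0.2319  -0.4012  -0.0183  -0.0811  -0.0408  -0.0497   0.0642  -0.4112
  0.1827   0.2121   0.1183   0.2316   0.1079   0.1890   0.2290   0.1589   0.1365   0.1402   0.1783   0.1138   0.1241   0.1498   0.1783   0.1983   0.1703   0.1647   0.1489   0.1472
  0.1663   0.0545   0.2422   0.3735   0.1646   0.2290   0.3134   0.2087   0.1180   0.1677   0.0681   0.1024   0.2049   0.1477   0.1660   0.1250   0.1787   0.2020   0.1513   0.0790
 -0.0031   0.1926   0.1879   0.1781  -0.0667   0.1589   0.2087   0.0108   0.1954  -0.1756  -0.1551   0.2006  -0.0526  -0.0440   0.0792   0.0669   0.0590   0.0307   0.0592  -0.0535
  0.2034   0.1363   0.1474   0.1402   0.1585   0.1365   0.1180   0.1954   0.1428   0.1104   0.1163   0.2002   0.1585   0.1652   0.1181   0.2149   0.0968   0.1468   0.1617   0.1241
 -0.3661   0.2266   0.1162   0.1021  -0.4674   0.1402   0.1677  -0.1756   0.1104  -0.6049  -0.6545   0.1685  -0.4256  -0.4173  -0.0061  -0.1033  -0.1927  -0.1410  -0.0903  -0.6119
 -0.3025   0.2094   0.0311   0.1230  -0.4864   0.1783   0.0681  -0.1551   0.1163  -0.6545  -0.4925   0.1292  -0.3801  -0.4011  -0.0058  -0.1066  -0.0575  -0.0721  -0.0025  -0.5350
  0.1295   0.3967   0.1214   0.0860   0.1629   0.1138   0.1024   0.2006   0.2002   0.1685   0.1292   0.3177   0.1071   0.2020   0.1262   0.2188   0.2393   0.2023   0.2461   0.1168
 -0.1467   0.2415   0.1841   0.1630  -0.2319   0.1241   0.2049  -0.0526   0.1585  -0.4256  -0.3801   0.1071  -0.2813  -0.2578   0.0141  -0.0497  -0.0074  -0.0184   0.0396  -0.4180
 -0.2248   0.2404   0.1307   0.1858  -0.4012   0.1498   0.1477  -0.0440   0.1652  -0.4173  -0.4011   0.2020  -0.2578  -0.3270  -0.0576  -0.0740   0.0001  -0.0379   0.0343  -0.4449
  0.0028   0.1987   0.2439   0.2656  -0.0183   0.1783   0.1660   0.0792   0.1181  -0.0061  -0.0058   0.1262   0.0141  -0.0576   0.1028   0.1083   0.1341   0.1377   0.0741  -0.0047
 -0.0462   0.1858   0.1499   0.1700  -0.0811   0.1983   0.1250   0.0669   0.2149  -0.1033  -0.1066   0.2188  -0.0497  -0.0740   0.1083   0.0164   0.0493   0.0443   0.0913  -0.0887
 -0.0865   0.2432   0.1840   0.1822  -0.0408   0.1703   0.1787   0.0590   0.0968  -0.1927  -0.0575   0.2393  -0.0074   0.0001   0.1341   0.0493   0.0275   0.0521   0.0788  -0.1171
 -0.0428   0.2006   0.1591   0.1946  -0.0497   0.1647   0.2020   0.0307   0.1468  -0.1410  -0.0721   0.2023  -0.0184  -0.0379   0.1377   0.0443   0.0521   0.0560   0.0625  -0.1065
 -0.0450   0.1436   0.1020   0.1817   0.0642   0.1489   0.1513   0.0592   0.1617  -0.0903  -0.0025   0.2461   0.0396   0.0343   0.0741   0.0913   0.0788   0.0625   0.0393  -0.0290
 -0.3649   0.2337   0.1387   0.1460  -0.4112   0.1472   0.0790  -0.0535   0.1241  -0.6119  -0.5350   0.1168  -0.4180  -0.4449  -0.0047  -0.0887  -0.1171  -0.1065  -0.0290  -0.6413
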