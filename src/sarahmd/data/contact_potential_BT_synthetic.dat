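# Synthetic stand-in contact-potential matrix ('BT' slot).
# NOT the published table of that name: a deterministic surrogate
# with the additive-plus-hydrophobicity structure of knowledge-based
# contact potentials, for testing and demonstration. Supply the
# literature matrix in this same format to reproduce published scores.
A R N D C Q E G H I L K M F P S T W Y V
 -0.6803  -0.1330  -0.2360  -0.3150  -0.7629  -0.2409  -0.3133  -0.4252  -0.3820  -0.8199  -0.8697  -0.2813  -0.7283  -0.7677  -0.5205  -0.4892  -0.5692  -0.5741  -0.3170  -0.8924
 -0.1330  -0.2712  -0.5214  -0.6137  -0.0255  -0.4678  -0.6887  -0.4513  -0.4715  -0.1780  -0.0663  -0.2654  -0.0858  -0.1180  -0.2769  -0.3935  -0.3485  -0.2909  -0.2464  -0.1636
 -0.2360  -0.5214  -0.5134  -0.4095  -0.2950  -0.5764  -0.4609  -0.3612  -0.5698  -0.2283  -0.2070  -0.4981  -0.3107  -0.2258  -0.5173  -0.4200  -0.3898  -0.4579  -0.2778  -0.1970
 -0.3150  -0.6137  -0.4095  -0.2165  -0.2753  -0.4420  -0.2107  -0.3166  -0.4572  -0.2200  -0.2979  -0.6720  -0.3889  -0.2424  -0.4030  -0.3538  -0.3621  -0.3474  -0.5021  -0.2402
 -0.7629  -0.0255  -0.2950  -0.2753  -0.8268  -0.2777  -0.2642  -0.6861  -0.2320  -1.0615  -1.0294  -0.2510  -0.7617  -0.9106  -0.4578  -0.5740  -0.6302  -0.4796  -0.5395  -1.0372
 -0.2409  -0.4678  -0.5764  -0.4420  -0.2777  -0.5725  -0.4840  -0.3358  -0.3938  -0.2097  -0.2167  -0.5027  -0.3294  -0.1557  -0.3446  -0.2638  -0.4060  -0.3945  -0.3600  -0.2605
 -0.3133  -0.6887  -0.4609  -0.2107  -0.2642  -0.4840  -0.1772  -0.2773  -0.3930  -0.2503  -0.1882  -0.6812  -0.3450  -0.2529  -0.3909  -0.3374  -0.4137  -0.4540  -0.4126  -0.1646
 -0.4252  -0.4513  -0.3612  -0.3166  -0.6861  -0.3358  -0.2773  -0.5302  -0.3783  -0.5715  -0.6319  -0.3590  -0.5855  -0.6106  -0.3471  -0.5216  -0.4881  -0.4453  -0.3479  -0.7234
 -0.3820  -0.4715  -0.5698  -0.4572  -0.2320  -0.3938  -0.3930  -0.3783  -0.4450  -0.2388  -0.3415  -0.4672  -0.2736  -0.3493  -0.3075  -0.4343  -0.4085  -0.4032  -0.4385  -0.1396
 -0.8199  -0.1780  -0.2283  -0.2200  -1.0615  -0.2097  -0.2503  -0.5715  -0.2388  -1.3496  -1.4407  -0.2197  -0.9537  -1.0304  -0.4957  -0.5328  -0.6220  -0.5916  -0.4288  -1.3375
 -0.8697  -0.0663  -0.2070  -0.2979  -1.0294  -0.2167  -0.1882  -0.6319  -0.3415  -1.4407  -1.2893  -0.1179  -0.9349  -1.1172  -0.4256  -0.7080  -0.5267  -0.5421  -0.4991  -1.1922
 -0.2813  -0.2654  -0.4981  -0.6720  -0.2510  -0.5027  -0.6812  -0.3590  -0.4672  -0.2197  -0.1179  -0.1624  -0.2359  -0.2096  -0.4009  -0.3668  -0.3740  -0.3418  -0.4136  -0.2364
 -0.7283  -0.0858  -0.3107  -0.3889  -0.7617  -0.3294  -0.3450  -0.5855  -0.2736  -0.9537  -0.9349  -0.2359  -0.7538  -0.7572  -0.4364  -0.4646  -0.5711  -0.4325  -0.4780  -0.9247
 -0.7677  -0.1180  -0.2258  -0.2424  -0.9106  -0.1557  -0.2529  -0.6106  -0.3493  -1.0304  -1.1172  -0.2096  -0.7572  -0.9109  -0.5137  -0.6385  -0.5491  -0.5450  -0.4226  -1.0817
 -0.5205  -0.2769  -0.5173  -0.4030  -0.4578  -0.3446  -0.3909  -0.3471  -0.3075  -0.4957  -0.4256  -0.4009  -0.4364  -0.5137  -0.4034  -0.4692  -0.3910  -0.5056  -0.4632  -0.4613
 -0.4892  -0.3935  -0.4200  -0.3538  -0.5740  -0.2638  -0.3374  -0.5216  -0.4343  -0.5328  -0.7080  -0.3668  -0.4646  -0.6385  -0.4692  -0.3478  -0.5362  -0.3673  -0.4979  -0.6418
 -0.5692  -0.3485  -0.3898  -0.3621  -0.6302  -0.4060  -0.4137  -0.4881  -0.4085  -0.6220  -0.5267  -0.3740  -0.5711  -0.5491  -0.3910  -0.5362  -0.5071  -0.4962  -0.4353  -0.6816
 -0.5741  -0.2909  -0.4579  -0.3474  -0.4796  -0.3945  -0.4540  -0.4453  -0.4032  -0.5916  -0.5421  -0.3418  -0.4325  -0.5450  -0.5056  -0.3673  -0.4962  -0.4799  -0.4537  -0.5582
 -0.3170  -0.2464  -0.2778  -0.5021  -0.5395  -0.3600  -0.4126  -0.3479  -0.4385  -0.4288  -0.4991  -0.4136  -0.4780  -0.4226  -0.4632  -0.4979  -0.4353  -0.4537  -0.4481  -0.4679
 -0.8924  -0.1636  -0.1970  -0.2402  -1.0372  -0.2605  -0.1646  -0.7234  -0.1396  -1.3375  -1.1922  -0.2364  -0.9247  -1.0817  -0.4613  -0.6418  -0.6816  -0.5582  -0.4679  -1.1771
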