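energy_keV,mu_photo_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm
1.000000000000000000e+01,4.002984930000000077e+03,1.152833937961302568e-01,1.305605000000000082e+01
2.000000000000000000e+01,5.003731162500000096e+02,1.112364592928925394e-01,3.264012500000000205e+00
3.000000000000000000e+01,1.482587011111111508e+02,1.075477461478471924e-01,1.450672222222222585e+00
4.000000000000000000e+01,6.254663953125000120e+01,1.041717533447840960e-01,8.160031250000000513e-01
5.000000000000000000e+01,3.202387944000000175e+01,1.010701648007827497e-01,5.222420000000000950e-01
6.000000000000000000e+01,1.853233763888889385e+01,9.821051860112969822e-02,3.626680555555556462e-01
7.000000000000000000e+01,1.167051000000000016e+01,9.556515608413623797e-02,2.664500000000000202e-01
8.000000000000000000e+01,7.818329941406250150e+00,9.311038538385570107e-02,2.040007812500000128e-01
9.000000000000000000e+01,5.491063004115226853e+00,9.082581075367876511e-02,1.611858024691358027e-01
1.000000000000000000e+02,4.002984930000000219e+00,8.869379109046879317e-02,1.305605000000000238e-01
1.100000000000000000e+02,3.007501825694966158e+00,8.669899992374605069e-02,1.079012396694214865e-01
1.200000000000000000e+02,2.316542204861111731e+00,8.482806566387926517e-02,9.066701388888891155e-02
1.300000000000000000e+02,1.822023181611287734e+00,8.306927576745989916e-02,7.725473372781065107e-02
1.400000000000000000e+02,1.458813750000000020e+00,8.141233213256343637e-02,6.661250000000000504e-02
1.500000000000000000e+02,1.186069608888888904e+00,7.984814780455010141e-02,5.802688888888889868e-02
1.600000000000000000e+02,9.772912426757812687e-01,7.836867718544875128e-02,5.100019531250000321e-02
1.700000000000000000e+02,8.147740545491551911e-01,7.696677356371531276e-02,4.517664359861592316e-02
1.800000000000000000e+02,6.863828755144033567e-01,7.563606903787080393e-02,4.029645061728395067e-02
1.900000000000000000e+02,5.836105744277592100e-01,7.437087288645762018e-02,3.616634349030471013e-02
2.000000000000000000e+02,5.003731162500000273e-01,7.316608520403505844e-02,3.264012500000000594e-02
2.100000000000000000e+02,4.322411111111109649e-01,7.201712322786166243e-02,2.960555555555555163e-02
2.200000000000000000e+02,3.759377282118707697e-01,7.091985825949839728e-02,2.697530991735537162e-02
2.300000000000000000e+02,3.290034462069531540e-01,6.987056146784831334e-02,2.468062381852551695e-02
2.400000000000000000e+02,2.895677756076389664e-01,6.886585716638497778e-02,2.266675347222222789e-02
2.500000000000000000e+02,2.561910355199999989e-01,6.790268240386262977e-02,2.088968000000000075e-02
2.600000000000000000e+02,2.277528977014109668e-01,6.697825190721429234e-02,1.931368343195266277e-02
2.700000000000000000e+02,2.033727038561194966e-01,6.609002757734350197e-02,1.790953360768175739e-02
2.800000000000000000e+02,1.823517187500000025e-01,6.523569187070166198e-02,1.665312500000000126e-02
2.900000000000000000e+02,1.641307527983927317e-01,6.441312450783746868e-02,1.552443519619500778e-02
3.000000000000000000e+02,1.482587011111111130e-01,6.362038203918704560e-02,1.450672222222222467e-02
3.100000000000000000e+02,1.343689345775569699e-01,6.285567987191958972e-02,1.358590010405827386e-02
3.200000000000000000e+02,1.221614053344726586e-01,6.211737642260391906e-02,1.275004882812500080e-02
3.300000000000000000e+02,1.113889565072209847e-01,6.140395911115329591e-02,1.198902662993572149e-02
3.400000000000000000e+02,1.018467568186443989e-01,6.071403195379493356e-02,1.129416089965398079e-02
3.500000000000000000e+02,9.336407999999998819e-02,6.004630454822912355e-02,1.065799999999999907e-02
3.600000000000000000e+02,8.579785943930041958e-02,5.939958227387413109e-02,1.007411265432098767e-02
3.700000000000000000e+02,7.902759816792688519e-02,5.877275755515091321e-02,9.536924762600439837e-03
3.800000000000000000e+02,7.295132180346990125e-02,5.816480205692535488e-02,9.041585872576177532e-03
3.900000000000000000e+02,6.748234005967733429e-02,5.757475969916064917e-02,8.583859303090073112e-03
4.000000000000000000e+02,6.254663953125000342e-02,5.700174039307028678e-02,8.160031250000001485e-03
4.100000000000000000e+02,5.808077262372861316e-02,5.644491441404484583e-02,7.766835217132659654e-03
4.200000000000000000e+02,5.403013888888887062e-02,5.590350733771094760e-02,7.401388888888887907e-03
4.300000000000000000e+02,5.034757857798683595e-02,5.537679547497847965e-02,7.061141157382368368e-03
4.400000000000000000e+02,4.699221602648384621e-02,5.486410175007758877e-02,6.743827479338842905e-03
4.500000000000000000e+02,4.392850403292182515e-02,5.436479197260061375e-02,6.447432098765433668e-03
4.600000000000000000e+02,4.112543077586914425e-02,5.387827146061010403e-02,6.170155954631379239e-03
4.700000000000000000e+02,3.855585881741039472e-02,5.340398197709903677e-02,5.910389316432775215e-03
4.800000000000000000e+02,3.619597195095487080e-02,5.294139894661468310e-02,5.666688368055556972e-03
4.900000000000000000e+02,3.402481049562682686e-02,5.249002892278707699e-02,5.437755102040816614e-03
5.000000000000000000e+02,3.202387943999999986e-02,5.204940728091863450e-02,5.222420000000000187e-03
5.100000000000000000e+02,3.017681683515389610e-02,5.161909611276820076e-02,5.019627066512879869e-03
5.200000000000000000e+02,2.846911221267637085e-02,5.119868230326322933e-02,4.828420857988165692e-03
5.300000000000000000e+02,2.688786669532566842e-02,5.078777577114621661e-02,4.647935208259166597e-03
5.400000000000000000e+02,2.542158798201493708e-02,5.038600785755591172e-02,4.477383401920439349e-03
5.500000000000000000e+02,2.406001460555972846e-02,4.999302984829077923e-02,4.316049586776859494e-03
5.600000000000000000e+02,2.279396484375000032e-02,4.960851161704345896e-02,4.163281250000000315e-03
5.700000000000000000e+02,2.161520646028737558e-02,4.923214037824752420e-02,4.018482610033857066e-03
5.800000000000000000e+02,2.051634409979909146e-02,4.886361953937536085e-02,3.881108799048751945e-03
5.900000000000000000e+02,1.949072169014358716e-02,4.850266764358261706e-02,3.750660729675380726e-03
6.000000000000000000e+02,1.853233763888888913e-02,4.814901739452897428e-02,3.626680555555556167e-03
6.100000000000000000e+02,1.763577096761402910e-02,4.780241475603581869e-02,3.508747648481590903e-03
6.200000000000000000e+02,1.679611682219462124e-02,4.746261811997763008e-02,3.396475026014568466e-03
6.300000000000000000e+02,1.600893004115226323e-02,4.712939753645625784e-02,3.289506172839506363e-03
6.400000000000000000e+02,1.527017566680908232e-02,4.680253400089454813e-02,3.187512207031250201e-03
6.500000000000000000e+02,1.457618545289030704e-02,4.648181879320061050e-02,3.090189349112426598e-03
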